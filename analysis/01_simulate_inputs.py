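#!/usr/bin/env python
"""Generate the synthetic study inputs: an old/new annotation pair with
planted boundary extensions, splicing events, gene merges and novel genes,
plus the machine-readable truth ledger.

Writes results/data/{old,new}.gtf and truth.json.
"""

import argparse
from pathlib import Path

import annoforge as af


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    p = af.SimParams(seed=args.seed)
    old, new, truth = af.generate_annotation_pair(p)
    args.outdir.mkdir(parents=True, exist_ok=True)
    af.write_gtf(old, args.outdir / "old.gtf")
    af.write_gtf(new, args.outdir / "new.gtf")
    truth.to_json(args.outdir / "truth.json")

    cats = {}
    for f in truth.transcripts.values():
        cats[f["category"]] = cats.get(f["category"], 0) + 1
    print(f"old annotation: {len(old.genes)} genes, {old.n_transcripts} transcripts")
    print(f"new annotation: {len(new.genes)} genes, {new.n_transcripts} transcripts")
    print(f"planted boundary categories: {cats}")
    print(f"planted merges: {len(truth.merges)}; novel genes: {len(truth.novel_genes)}")
    print(f"genes with planted splicing events: {len(truth.events)}")
    print(f"wrote {args.outdir}/old.gtf, new.gtf, truth.json")


if __name__ == "__main__":
    main()
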