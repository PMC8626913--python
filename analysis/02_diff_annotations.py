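#!/usr/bin/env python
"""Compare the old and new annotations: intron-chain transcript matching,
TSS/TTS extension classification, exonic-coverage change, merged-gene
detection and gene correspondence.

Reads results/data/{old,new}.gtf; writes matches.tsv, extensions_summary.tsv,
gene_coverage.tsv, merges.tsv and correspondence.tsv under results/diff/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import annoforge as af


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/diff"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    old = af.read_gtf(args.data / "old.gtf", label="old")
    new = af.read_gtf(args.data / "new.gtf", label="new")

    matches = af.match_transcripts(old, new)
    pd.DataFrame(
        [
            {
                "old_id": m.old_id,
                "new_id": m.new_id or "",
                "category": m.category,
                "ambiguous": m.ambiguous,
                "tss_delta": m.extension.tss_delta if m.extension else "",
                "tts_delta": m.extension.tts_delta if m.extension else "",
            }
            for m in matches
        ]
    ).to_csv(args.outdir / "matches.tsv", sep="\t", index=False)

    s = af.summarize_extensions(matches)
    pd.DataFrame(
        [{"category": c, "n": n} for c, n in s.counts.items()]
    ).to_csv(args.outdir / "extensions_summary.tsv", sep="\t", index=False)
    print("transcript match categories:", s.counts)
    print(
        f"median extension: TTS {s.median_tts_extension} nt, "
        f"TSS {s.median_tss_extension} nt"
    )

    table = af.gene_correspondence(old, new)
    cov = af.gene_coverage_change(old, new, table)
    pd.DataFrame([vars(c) for c in cov]).to_csv(
        args.outdir / "gene_coverage.tsv", sep="\t", index=False
    )
    klass = pd.Series([c.klass for c in cov]).value_counts().to_dict()
    print(f"exonic coverage change over {len(cov)} one-to-one genes: {klass}")

    merges = af.detect_merged_genes(old, new)
    pd.DataFrame(
        [
            {"new_gene_id": m.new_gene_id,
             "old_gene_ids": ",".join(sorted(m.old_gene_ids)),
             "overlap_nt": json.dumps(m.overlap_nt, sort_keys=True)}
            for m in merges
        ]
    ).to_csv(args.outdir / "merges.tsv", sep="\t", index=False)

    rows = [{"gene_id": g, "side": "old", "class": c} for g, c in table.old_class.items()]
    rows += [{"gene_id": g, "side": "new", "class": c} for g, c in table.new_class.items()]
    pd.DataFrame(rows).to_csv(args.outdir / "correspondence.tsv", sep="\t", index=False)
    print(f"detected {len(merges)} merged gene models; "
          f"{sum(1 for c in table.new_class.values() if c == 'new_gene')} novel genes; "
          f"{len(table.pairs)} one-to-one pairs")

    truth_path = args.data / "truth.json"
    if truth_path.exists():
        truth = json.load(open(truth_path))
        planted = {k: sorted(v) for k, v in truth["merges"].items()}
        found = {m.new_gene_id: sorted(m.old_gene_ids) for m in merges}
        print("planted merges recovered:",
              sum(1 for k, v in planted.items() if found.get(k) == v),
              "/", len(planted))


if __name__ == "__main__":
    main()
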