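# annoforge

Tools for quantifying what changes when a genome annotation is upgraded
with long-read (Iso-Seq) evidence — written for transcriptomics analysts
working on non-model organisms (the motivating system is the ant
*Harpegnathos saltator* brain), where refined gene models shift every
downstream analysis: splicing, 3′ end calls, and 3′-biased single-cell
quantification.

The library implements, with planted-truth simulations and tests around
every step:

- **Annotation diff** — transcripts of an old and a new annotation are
  matched iff they share their *intron chain* (all internal exon
  boundaries; chrom and strand equal), so only the outer boundaries may
  move. Matched pairs get signed, strand-aware boundary deltas and a
  category (`no_change`, `tss_extended`, `tts_extended`, `both_extended`,
  `contracted`); per-gene exonic coverage change, merged-gene detection
  (one new gene overlapping ≥ 2 old genes' exonic unions on one strand)
  and a one_to_one/merged/new/lost/ambiguous gene correspondence.
- **Splicing** — SUPPA-style local event classification (SE, MX, A5, A3,
  RI, AF, AL) from isoform pairs with locus-level deduplication; the
  retained-intron homology filter (drop the retaining isoform iff the
  spliced form has strictly higher query coverage); isoform proportions
  per replicate, condition means, maxDprop, and the strict DTU threshold
  filter (padj < 10⁻⁵, maxDprop > 0.5, replication support > 0.8).
- **dT-seq TTS validation** — polyT read filtering (≥ 5 T in the first 6
  bases, one-mismatch trimming), strand-aware coverage, peak calling with
  the *most downstream* position at ≥ 90% of the peak maximum as summit,
  and retention of dT peaks whose summit is downstream of or equal to
  every overlapping hexamer-library summit — i.e. peaks with no hex signal
  downstream, separating true polyA junctions from internal A-stretches.
- **Single-cell metrics** — QC (≥ 200 genes and ≥ 500 UMIs per cell, genes
  in ≥ 3 cells), log-normalization (scale factor 10,000), detection
  fractions, pseudobulk %UMI per (sample, cluster), and Seurat-style
  marker / within-cluster DE calling (Wilcoxon rank-sum, Bonferroni;
  min.pct 0.25, logFC 1, padj < 0.05 for markers; padj < 0.01 for DE).
- **Synthetic data** — a seeded generator emitting annotation pairs, dT/hex
  read sets, abundance tables and UMI matrices together with a truth
  ledger, used by the analysis scripts, the tests and the acceptance
  script.

## Worked example

```python
import annoforge as af

p = af.SimParams(seed=0)                      # study conditions, desk scale
old, new, truth = af.generate_annotation_pair(p)
matches = af.match_transcripts(old, new)
s = af.summarize_extensions(matches)
print(s.counts)
print(s.median_tts_extension, s.median_tss_extension)
```

prints

```
{'no_change': 268, 'tss_extended': 49, 'tts_extended': 129, 'both_extended': 19, 'contracted': 25, 'no_internal_match': 10}
265.0 37.5
```

— of 500 old transcripts, 129 grew at the 3′ end and 49 at the 5′ end,
with median growth of 265 nt (TTS) and 37.5 nt (TSS); the ten transcripts
without an intron-chain match belong to genes that were merged in the new
annotation. Every category and signed delta equals the generator's ledger
exactly.

The full analysis is scripted:

```bash
python analysis/01_simulate_inputs.py      # annotation pair + truth ledger
python analysis/02_diff_annotations.py     # matching, extensions, merges
python analysis/03_splice_events_dtu.py    # AS events, RI filter, DTU
python analysis/04_validate_tts.py         # dT-seq peak calling + recovery
python analysis/05_single_cell_metrics.py  # QC, markers, DE, pseudobulk
```

Each script states what it found and writes its tables under `results/`.

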