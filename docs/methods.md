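# Methods

## Scope and model

`annoforge` re-implements, as a tested library, the bespoke computations of
an annotation-upgrade study: comparing an "old" and a "new" genome
annotation of the ant *Harpegnathos saltator* after long-read (Iso-Seq)
refinement, and quantifying the downstream consequences for splicing, 3′
end (TTS) validation, and single-cell RNA-seq. The real study's inputs —
PacBio long reads, aligned Illumina libraries, 10x matrices — are replaced
by a synthetic-data generator that plants ground truth for every quantity
the pipeline measures, so correctness is assessed as exact (or bounded)
recovery of planted facts rather than as reproduction of the study's
dataset-specific counts.

All genomic coordinates are 0-based half-open internally; GTF I/O converts
at the boundary. "Downstream" always means larger coordinates on `+` and
smaller on `-`.

## Annotation comparison

Two transcripts match iff they share chrom, strand, and their full **intron
chain** (the ordered splice-junction intervals; the outermost boundaries
are free). Single-exon transcripts, which have no internal boundaries, pair
by same-strand exonic overlap and only when the candidate is unique —
overlap is the weakest defensible criterion and uniqueness prevents
arbitrary pairing. When several new transcripts share an old intron chain,
the candidate maximizing the summed boundary growth wins (ties broken by
transcript id) and the match is flagged `ambiguous`; since the comparison
reports extensions, the most-extended compatible model is the conservative
choice for extension statistics.

Boundary changes are signed, strand-aware deltas: positive `tss_delta`
means the 5′ boundary moved outward, positive `tts_delta` the 3′ boundary.
Categories are `no_change`, `tss_extended`, `tts_extended`,
`both_extended`, `contracted`; mixed-sign pairs are categorized by their
positive delta(s) (the five-way scheme has no mixed class) with the
negative delta retained in the record. Extension medians are computed over
strictly positive deltas only and reported as undefined (never 0) when no
transcript extended.

A new gene is a **merge candidate** when its exonic union overlaps the
exonic unions of ≥ 2 old genes on the same strand by at least `min_overlap`
nt (default 1 nt — the study reviewed merges manually and states no
threshold). Gene correspondence is a greedy partition: merge participants →
`merged`; an old gene overlapping exactly one non-merged new gene that
overlaps only it → `one_to_one`; no overlap → `lost`/`new_gene`; everything
else → `ambiguous`. Exonic coverage change (`same`/`more`/`fewer`, fold
change) is computed on one-to-one pairs only.

## Splicing events

Seven local event types (SE, MX, A5, A3, RI, AF, AL) are generated
pairwise between isoforms and deduplicated by `(type, signature)` within a
gene, with supporting isoform sets merged — locus-level semantics, so a
gene counts once per type regardless of multiplicity. The definitions are
splice-site exact:

- **SE**: an internal exon whose two flanking introns' outer sites form a
  single intron of the partner.
- **RI**: a single exon spanning exactly two consecutive exons of the
  partner plus the intervening intron (outer boundaries equal); the
  *inclusion* isoform is the retainer.
- **A5/A3**: two introns sharing one splice site and differing at the
  donor (A5) or acceptor (A3), *with the two alternative-side exons
  overlapping*.
- **AF/AL**: distinct, **non-overlapping** terminal (first/last) exons
  splicing to/from the same site of a shared neighbouring exon.
- **MX**: two non-overlapping internal exons, each private to one isoform,
  with identical outer flanking donor and acceptor.

The exon-overlap condition on A5/A3 and the terminal/non-overlap condition
on AF/AL disambiguate the shared-site cases: terminal exons differing only
in length are A5/A3, not AF/AL, and shared-site intron pairs whose
alternative exons are non-overlapping and not terminal emit nothing (those
configurations belong to MX or are complex). An independently written
exhaustive enumerator — literal nested loops in transcript-oriented
coordinates, versus the production scanner's strand-conditional genomic
arithmetic — must agree exactly on every random gene tested.

**Retained-intron filter.** Suspected pre-mRNA isoforms are removed when
the intron-spliced partner has *strictly* higher homology query coverage
(ties keep the isoform). With several spliced partners the highest-coverage
one is used — the most conservative removal criterion. Missing coverage
entries skip the decision with a warning; a gene is never emptied (the
highest-coverage isoform is kept and flagged). The filter never adds
transcripts and is idempotent.

**DTU.** Isoform proportions are per-replicate abundances over the gene
total (samples with zero gene total are excluded, not imputed), averaged
unweighted within condition. `maxDprop` is the largest between-condition
difference in mean isoform proportion. The DTU gene filter applies the
published thresholds — padj < 1e-5, maxDprop > 0.5, replication support
> 0.8, all strict — to externally supplied test statistics; the statistical
test itself is out of scope.

## dT-seq TTS validation

The protocol sequences the same fragmented polyA+ RNA twice: oligo-dT
primed reads (after polyT filtering/trimming) mark polyA junctions; random
hexamer reads sample transcript bodies. The polyT rule keeps a read iff its
first 6 bases contain ≥ 5 T, and trims the leading T run tolerating one
non-T interruption (only when followed by further T) — both knobs are
parameters.

Coverage is per (chrom, strand); dT and hex are never pooled across
strands. A **peak** is a maximal run of consecutively covered positions;
**tentative summits** are positions with coverage ≥ 90% of the peak
maximum; the **summit** is the most downstream tentative summit. Integer
counts make the 0.9 × max comparison exactly representable. A dT peak is
retained iff it overlaps ≥ 1 hex peak and its summit is downstream of or
equal to the summit of *every* overlapping hex peak — the intent is "no
hex signal downstream", which is the signature separating true polyA
junctions from internal A-stretches (where transcription, and therefore
hex coverage, continues). Peaks with no hex overlap are discarded
(`keep_no_overlap` exposes the sensitivity-analysis variant). Retained-peak
reads, 5′-base reduction, genomic context (3′ UTR vs CDS vs other, by
summit position, UTR3 winning), and TTS metaprofiles (±100 nt, rows
oriented 5′→3′, zero-padded and flagged at contig edges) follow.

## Single-cell metrics

QC keeps genes detected in ≥ 3 cells of the raw matrix first, then cells
with ≥ 200 detected genes and ≥ 500 UMIs evaluated on the gene-filtered
matrix. The gene-then-cell order matches the usual create-then-subset
workflow; the two orders differ only at the margins, and strict idempotency
is consequently a property of realistic matrices (asserted on the
simulated study conditions) rather than a theorem. Normalization is
`log(1 + count/cell_total × 10,000)`, natural log by default with a log2
variant.

Marker calling mirrors the Seurat v3 conventions: detection fractions
`pct_in`/`pct_out`; fold change
`log((mean(expm1 x_in)+1)/(mean(expm1 x_out)+1))` on normalized values
(natural log); candidates need `max(pct_in, pct_out) ≥ 0.25` and
`|logFC| ≥ 1` (positive only for markers); a two-sided Wilcoxon rank-sum
test (normal approximation with tie and continuity correction — exact
tests are unnecessary at these group sizes) on normalized values; and
Bonferroni over the genes actually tested after the pre-filters (a flag
switches to all genes). Markers are retained at padj < 0.05. Within-cluster
condition DE reuses the machinery two-sidedly with the tool-default
pre-filters (min.pct 0.1, logFC 0.25) at padj < 0.01, reported from the
alphabetically first condition; clusters missing a condition or with < 3
cells per group are skipped. Pseudobulk %UMI is the gene's UMIs over all
UMIs in each (sample, cluster) stratum, × 100; strata sum to 100% over
genes by construction.

## Synthetic data generator

One explicitly seeded `numpy` Generator per call; no global state;
identical parameters give byte-identical outputs. Defaults are the study
conditions at desk scale:

- **Annotation pair**: 500 single-isoform background genes (multi-isoform
  background would plant unledgered events), exons 80–300 nt, introns
  200–1500 nt, intergenic gaps 5–10 kb (so boundary growth, capped at
  2 kb, can never make distinct genes overlap — planted merges are the only
  merges). Boundary categories drawn with probabilities (no_change 0.45,
  tss 0.12, tts 0.30, both 0.08, contracted 0.05) shaped on the study's
  reported proportions; extension lengths lognormal with medians 251 nt
  (TTS) and 31 nt (TSS) — the study's reported medians — and σ = 0.8.
  8 planted events per type as dedicated two-isoform genes whose pairwise
  event content is exactly the planted event; 5 merged pairs fused by a
  bridging isoform; 12 novel genes in fresh sequence space. The ledger is
  self-checked against the emitted pair before returning.
- **dT/hex reads**: placed on the genomic span of each transcript
  (splicing not modelled). dT first mates end at the TTS plus
  `Normal(0, σ)` jitter (default σ = 20 nt, 20 reads/TTS). Hex 5′ ends are
  uniform over the body; priming within 40 nt of the polyA junction is
  treated as failing size selection, so hex coverage decays before the
  TTS, and two terminal-fragment reads guarantee hex signal abutting every
  dT peak. Each internal A-stretch site (50 by default) gets a dT pile
  ending at the site plus a strong hex pile overlapping it and continuing
  downstream — the configuration the categorization must discard. In the
  noiseless limit this construction makes retained peaks provably equal
  the true TTS set.
- **Abundances**: per-gene expression lognormal (median 50 TPM); replicate
  proportions Dirichlet around a condition target (concentration 300, i.e.
  tight replicates); DTU genes swap 0.6 of proportion mass between their
  two isoforms across conditions; 3 replicates per condition.
- **UMI matrix**: 1000 genes × 4 clusters × 200 cells,
  negative-binomial (size 2) with lognormal baseline means and lognormal
  cell depths (σ = 0.3; typical cell ≈ 1600 UMIs, so QC exercises but
  rarely removes cells). Markers: 10 per cluster at 8-fold in-cluster
  elevation with the in-cluster mean chosen so detection is 40%
  (`μ = r((1-d)^{-1/r}-1)`). Condition-biased genes: 10 at 4-fold / 50%
  detection, shared across clusters. Worker/gamergate labels are random per
  cell, 2 samples per condition.

What the generator does *not* emulate: spliced read placement, sequence
content (beyond the polyT prefix logic), ambient RNA/doublets, batch
effects, overdispersed replicate structure, or correlated genes. Passing
recovery tests therefore demonstrates the correctness of the computations
under their stated definitions, not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

The test-suite and acceptance sizes (500 genes for oracle agreement, 500
transcripts for extension recovery, 10 seeds × 6 merges, 50 TTSs + 50
A-stretches, 1000 random coverage tracks, 100 label permutations, 800-cell
matrices) were chosen as the smallest scales at which the recovery
statistics are stable; the whole suite runs in a few seconds. Ties are
broken deterministically everywhere (lexicographic ids); medians use the
standard midpoint convention; peak summit thresholds use exact comparisons
on integer counts. Degenerate inputs (empty annotations, empty tracks,
zero-total genes, single-condition clusters) return empty/undefined results
rather than erroring, except where a contract is violated (negative
abundances, zero-total cells after QC).

## Known limitations

- Single-exon transcript matching by unique overlap can neither split nor
  merge transcripts; many-to-one matching is deliberately excluded.
- Event classification is pairwise; events only expressible against a
  full splice graph (e.g. nested alternatives spanning three isoforms) are
  reported as their pairwise projections.
- The Wilcoxon normal approximation is inaccurate for groups ≪ 10 cells;
  the group-size floor (3) mirrors the upstream tool rather than a power
  guarantee.
- `classify_peak_context` scans transcripts linearly; it is adequate at
  annotation scales of ~10⁴ transcripts but not indexed for larger ones.
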