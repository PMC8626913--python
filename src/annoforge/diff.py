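"""Old-vs-new annotation comparison.

Transcript matching follows the internal-exon-boundary criterion: a
multi-exon transcript pairs with a transcript whose chrom, strand and full
intron chain are identical, so only the outermost (TSS/TTS) boundaries may
differ.  Single-exon transcripts, which have no internal boundaries, pair by
unique same-strand exonic overlap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, FrozenSet, List, Optional, Tuple

from .models import (
    GenomeAnnotation,
    TranscriptModel,
    exonic_union,
    exonic_union_length,
    interval_list_overlap,
)

CATEGORIES = (
    "no_change",
    "tss_extended",
    "tts_extended",
    "both_extended",
    "contracted",
    "no_internal_match",
)


@dataclass(frozen=True)
class ExtensionRecord:
    """Signed boundary movements; positive means the transcript grew outward."""

    tss_delta: int
    tts_delta: int


@dataclass
class TranscriptMatch:
    old_id: str
    new_id: Optional[str]
    category: str
    ambiguous: bool = False
    extension: Optional[ExtensionRecord] = None


@dataclass
class ExtensionSummary:
    counts: Dict[str, int]
    median_tss_extension: Optional[float]
    median_tts_extension: Optional[float]


@dataclass
class GeneCoverageChange:
    old_gene_id: str
    new_gene_id: str
    old_nt: int
    new_nt: int
    fold_change: float
    klass: str  # same | more | fewer


@dataclass
class MergeRecord:
    new_gene_id: str
    old_gene_ids: FrozenSet[str]
    overlap_nt: Dict[str, int]


@dataclass
class CorrespondenceTable:
    old_class: Dict[str, str] = field(default_factory=dict)
    new_class: Dict[str, str] = field(default_factory=dict)
    pairs: List[Tuple[str, str]] = field(default_factory=list)
    merges: List[MergeRecord] = field(default_factory=list)


def boundary_deltas(old_t: TranscriptModel, new_t: TranscriptModel) -> ExtensionRecord:
    """Strand-aware signed distances the 5' and 3' boundaries moved outward."""
    if old_t.strand == "+":
        tss_delta = old_t.span_start - new_t.span_start
        tts_delta = new_t.span_end - old_t.span_end
    else:
        tss_delta = new_t.span_end - old_t.span_end
        tts_delta = old_t.span_start - new_t.span_start
    return ExtensionRecord(tss_delta=tss_delta, tts_delta=tts_delta)


def classify_extension(
    old_t: TranscriptModel, new_t: TranscriptModel
) -> Tuple[str, ExtensionRecord]:
    """Assign one of the boundary-change categories to a matched pair.

    Mixed-sign pairs (one boundary out, the other in) are categorized by the
    positive delta(s); the contraction stays visible in the record.
    """
    rec = boundary_deltas(old_t, new_t)
    pos_tss, pos_tts = rec.tss_delta > 0, rec.tts_delta > 0
    if rec.tss_delta == 0 and rec.tts_delta == 0:
        cat = "no_change"
    elif pos_tss and pos_tts:
        cat = "both_extended"
    elif pos_tss:
        cat = "tss_extended"
    elif pos_tts:
        cat = "tts_extended"
    else:
        cat = "contracted"
    return cat, rec


def match_transcripts(
    old: GenomeAnnotation, new: GenomeAnnotation
) -> List[TranscriptMatch]:
    """One match decision per old transcript.

    Several new transcripts may share an old intron chain; the candidate
    maximizing (tss_delta + tts_delta) wins (ties broken lexicographically by
    transcript_id) and the match is flagged ambiguous.
    """
    by_chain: Dict[Tuple, List[TranscriptModel]] = defaultdict(list)
    single_by_loc: Dict[Tuple[str, str], List[TranscriptModel]] = defaultdict(list)
    for t in new.transcripts():
        if len(t.exons) > 1:
            by_chain[(t.chrom, t.strand, t.intron_chain)].append(t)
        else:
            single_by_loc[(t.chrom, t.strand)].append(t)

    matches: List[TranscriptMatch] = []
    for old_t in old.transcripts():
        if len(old_t.exons) > 1:
            candidates = by_chain.get((old_t.chrom, old_t.strand, old_t.intron_chain), [])
            ambiguous = len(candidates) > 1
        else:
            candidates = [
                c
                for c in single_by_loc.get((old_t.chrom, old_t.strand), [])
                if c.span_start < old_t.span_end and old_t.span_start < c.span_end
            ]
            # single-exon pairing must be unique to be defensible
            if len(candidates) != 1:
                candidates = []
            ambiguous = False
        if not candidates:
            matches.append(
                TranscriptMatch(old_t.transcript_id, None, "no_internal_match")
            )
            continue
        best = min(
            candidates,
            key=lambda c: (
                -(boundary_deltas(old_t, c).tss_delta
                  + boundary_deltas(old_t, c).tts_delta),
                c.transcript_id,
            ),
        )
        cat, rec = classify_extension(old_t, best)
        matches.append(
            TranscriptMatch(
                old_t.transcript_id, best.transcript_id, cat, ambiguous, rec
            )
        )
    return matches


def summarize_extensions(matches: List[TranscriptMatch]) -> ExtensionSummary:
    """Category counts plus medians of the strictly positive deltas.

    Medians are ``None`` (undefined), never 0, when no transcript extended.
    """
    counts = {c: 0 for c in CATEGORIES}
    tss_pos: List[int] = []
    tts_pos: List[int] = []
    for m in matches:
        counts[m.category] += 1
        if m.extension is not None:
            if m.extension.tss_delta > 0:
                tss_pos.append(m.extension.tss_delta)
            if m.extension.tts_delta > 0:
                tts_pos.append(m.extension.tts_delta)
    return ExtensionSummary(
        counts=counts,
        median_tss_extension=median(tss_pos) if tss_pos else None,
        median_tts_extension=median(tts_pos) if tts_pos else None,
    )


def gene_coverage_change(
    old: GenomeAnnotation,
    new: GenomeAnnotation,
    correspondence: CorrespondenceTable,
) -> List[GeneCoverageChange]:
    """Exonic-nt change for every one-to-one gene pair."""
    out: List[GeneCoverageChange] = []
    for old_gid, new_gid in correspondence.pairs:
        old_nt = exonic_union_length(old.genes[old_gid])
        new_nt = exonic_union_length(new.genes[new_gid])
        if new_nt > old_nt:
            klass = "more"
        elif new_nt < old_nt:
            klass = "fewer"
        else:
            klass = "same"
        out.append(
            GeneCoverageChange(
                old_gene_id=old_gid,
                new_gene_id=new_gid,
                old_nt=old_nt,
                new_nt=new_nt,
                fold_change=new_nt / old_nt,
                klass=klass,
            )
        )
    return out


def _unions_by_location(
    ann: GenomeAnnotation,
) -> Dict[Tuple[str, str], List[Tuple[str, List[Tuple[int, int]]]]]:
    grouped: Dict[Tuple[str, str], List[Tuple[str, List[Tuple[int, int]]]]] = (
        defaultdict(list)
    )
    for gid in sorted(ann.genes):
        gene = ann.genes[gid]
        grouped[(gene.chrom, gene.strand)].append((gid, exonic_union(gene)))
    return grouped


def detect_merged_genes(
    old: GenomeAnnotation, new: GenomeAnnotation, min_overlap: int = 1
) -> List[MergeRecord]:
    """New genes whose exonic union overlaps >=2 old genes on the same strand."""
    old_by_loc = _unions_by_location(old)
    records: List[MergeRecord] = []
    for new_gid in sorted(new.genes):
        gene = new.genes[new_gid]
        new_union = exonic_union(gene)
        overlaps: Dict[str, int] = {}
        for old_gid, old_union in old_by_loc.get((gene.chrom, gene.strand), []):
            nt = interval_list_overlap(new_union, old_union)
            if nt >= min_overlap:
                overlaps[old_gid] = nt
        if len(overlaps) >= 2:
            records.append(
                MergeRecord(new_gid, frozenset(overlaps), overlaps)
            )
    return records


def gene_correspondence(
    old: GenomeAnnotation, new: GenomeAnnotation, min_overlap: int = 1
) -> CorrespondenceTable:
    """Partition both gene sets into one_to_one/merged/new_gene/lost/ambiguous."""
    merges = detect_merged_genes(old, new, min_overlap=min_overlap)
    table = CorrespondenceTable(merges=merges)

    old_by_loc = _unions_by_location(old)
    new_by_loc = _unions_by_location(new)
    old_neighbors: Dict[str, List[str]] = {gid: [] for gid in old.genes}
    new_neighbors: Dict[str, List[str]] = {gid: [] for gid in new.genes}
    for loc, new_entries in new_by_loc.items():
        for new_gid, new_union in new_entries:
            for old_gid, old_union in old_by_loc.get(loc, []):
                if interval_list_overlap(new_union, old_union) >= 1:
                    old_neighbors[old_gid].append(new_gid)
                    new_neighbors[new_gid].append(old_gid)

    merged_new = {m.new_gene_id for m in merges}
    merged_old = {gid for m in merges for gid in m.old_gene_ids}
    for gid in merged_old:
        table.old_class[gid] = "merged"
    for gid in merged_new:
        table.new_class[gid] = "merged"

    for old_gid in sorted(old.genes):
        if old_gid in table.old_class:
            continue
        nbrs = old_neighbors[old_gid]
        if not nbrs:
            table.old_class[old_gid] = "lost"
        elif (
            len(nbrs) == 1
            and nbrs[0] not in merged_new
            and new_neighbors[nbrs[0]] == [old_gid]
        ):
            table.old_class[old_gid] = "one_to_one"
            table.new_class[nbrs[0]] = "one_to_one"
            table.pairs.append((old_gid, nbrs[0]))
        else:
            table.old_class[old_gid] = "ambiguous"

    for new_gid in sorted(new.genes):
        if new_gid in table.new_class:
            continue
        if not new_neighbors[new_gid]:
            table.new_class[new_gid] = "new_gene"
        else:
            table.new_class[new_gid] = "ambiguous"
    return table
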