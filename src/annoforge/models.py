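"""Strand-aware gene-model containers.

All coordinates are 0-based half-open on the genome; GTF conversion happens
only at the I/O boundary (:mod:`annoforge.gtf`).  "Downstream" always means
larger coordinates on ``+`` and smaller coordinates on ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """An annotation violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def is_downstream_or_equal(a: int, b: int, strand: str) -> bool:
    """True iff position ``a`` is downstream of or equal to ``b`` on ``strand``."""
    return a >= b if strand == "+" else a <= b


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus optional CDS intervals.

    Exons are kept in genomic coordinate order regardless of strand; 5'/3'
    accessors (:attr:`tss`, :attr:`tts`) are strand-aware base positions.
    """

    transcript_id: str
    gene_id: str
    exons: List[Exon]
    cds: Optional[List[GenomicInterval]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.interval.chrom for e in self.exons}
        strands = {e.interval.strand for e in self.exons}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} mixes strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
            if b.start == a.end:
                raise ValidationError(
                    f"transcript {self.transcript_id} has book-ended exons at {a.end}"
                )
        if self.cds:
            self.cds = sorted(self.cds, key=lambda c: c.start)

    @property
    def chrom(self) -> str:
        return self.exons[0].interval.chrom

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """5'-most transcribed base (max coordinate on ``-``)."""
        return self.span_start if self.strand == "+" else self.span_end - 1

    @property
    def tts(self) -> int:
        """3'-most transcribed base (min coordinate on ``-``)."""
        return self.span_end - 1 if self.strand == "+" else self.span_start

    @property
    def intron_chain(self) -> Tuple[Tuple[int, int], ...]:
        """Gaps between consecutive exons, as half-open intervals.

        Identity of this tuple (plus chrom and strand) is what "same internal
        exon boundaries" means for transcript matching.
        """
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def cds_span(self) -> Optional[Tuple[int, int]]:
        if not self.cds:
            return None
        return self.cds[0].start, self.cds[-1].end

    def utr3_interval(self) -> Optional[Tuple[int, int]]:
        """Genomic interval between the CDS end and the TTS (strand-aware)."""
        span = self.cds_span
        if span is None:
            return None
        cds_start, cds_end = span
        if self.strand == "+":
            if cds_end < self.span_end:
                return cds_end, self.span_end
        else:
            if self.span_start < cds_start:
                return self.span_start, cds_start
        return None


@dataclass
class GeneModel:
    gene_id: str
    transcripts: List[TranscriptModel]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {self.gene_id} transcripts disagree on chrom/strand"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span_start(self) -> int:
        return min(t.span_start for t in self.transcripts)

    @property
    def span_end(self) -> int:
        return max(t.span_end for t in self.transcripts)


@dataclass
class GenomeAnnotation:
    genes: Dict[str, GeneModel] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for gene in self.genes.values():
            for t in gene.transcripts:
                if t.transcript_id in seen:
                    raise ValidationError(
                        f"duplicate transcript_id {t.transcript_id} in genes "
                        f"{seen[t.transcript_id]} and {gene.gene_id}"
                    )
                seen[t.transcript_id] = gene.gene_id

    def transcripts(self) -> Iterable[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts

    def transcript_index(self) -> Dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts()}

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.genes == other.genes


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of half-open intervals as a sorted, disjoint list."""
    out: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def exonic_union(gene: GeneModel) -> List[Tuple[int, int]]:
    """Merged union of all exon intervals over all transcripts of a gene."""
    return merge_intervals(
        (e.start, e.end) for t in gene.transcripts for e in t.exons
    )


def exonic_union_length(gene: GeneModel) -> int:
    """Number of nucleotides covered by exons of any transcript of the gene."""
    return sum(end - start for start, end in exonic_union(gene))


def interval_list_overlap(
    a: List[Tuple[int, int]], b: List[Tuple[int, int]]
) -> int:
    """Total overlap (nt) between two sorted disjoint interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total
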