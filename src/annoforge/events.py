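"""Local alternative-splicing event classification (SUPPA-style, pairwise).

Seven event types are recognised between isoform pairs of one gene:

* SE  — skipped exon: one isoform includes an internal exon whose flanking
  introns share their outer splice sites with a single intron of the other.
* RI  — retained intron: one isoform carries a single exon spanning exactly
  two consecutive exons of the other plus the intervening intron.
* A5 / A3 — alternative 5'/3' splice site: two introns share one splice site
  and differ at the other, with the two alternative-side exons overlapping.
* MX  — mutually exclusive exons: two non-overlapping internal exons, each
  present in exactly one isoform, sharing flanking donor and acceptor.
* AF / AL — alternative first/last exon: distinct, non-overlapping terminal
  exons splicing to/from the same site of a shared neighbouring exon.

Events are generated pairwise and deduplicated by (type, signature) within a
gene, with supporting transcript sets merged, so multiplicities follow
locus-level semantics.  Shared-site intron pairs whose alternative exons are
non-overlapping and not terminal emit nothing: those configurations are
covered by MX or are complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Set, Tuple

from .models import GeneModel, GenomeAnnotation, TranscriptModel

log = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "MX", "A5", "A3", "RI", "AF", "AL")


@dataclass
class ASEvent:
    event_type: str
    gene_id: str
    signature: Tuple[int, ...]
    inclusion_transcripts: Set[str] = field(default_factory=set)
    exclusion_transcripts: Set[str] = field(default_factory=set)


@dataclass
class RIFilterDecision:
    ri_transcript_id: str
    no_ri_transcript_id: str
    coverage_with_ri: float
    coverage_without_ri: float
    removed: bool
    kept_to_preserve_gene: bool = False


def _intervals_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


class _TxView:
    """Cached per-transcript structure used by the pairwise scanner."""

    def __init__(self, t: TranscriptModel):
        self.id = t.transcript_id
        self.strand = t.strand
        self.exons: List[Tuple[int, int]] = [(e.start, e.end) for e in t.exons]
        self.exon_set = set(self.exons)
        self.introns: List[Tuple[int, int]] = list(t.intron_chain)
        self.intron_set = set(self.introns)
        # exon adjacent to each intron on its left/right (genomic)
        self.left_exon = {iv: self.exons[i] for i, iv in enumerate(self.introns)}
        self.right_exon = {iv: self.exons[i + 1] for i, iv in enumerate(self.introns)}
        self.first_exon = self.exons[0] if self.strand == "+" else self.exons[-1]
        self.last_exon = self.exons[-1] if self.strand == "+" else self.exons[0]

    def donor(self, intron: Tuple[int, int]) -> int:
        return intron[0] if self.strand == "+" else intron[1]

    def acceptor(self, intron: Tuple[int, int]) -> int:
        return intron[1] if self.strand == "+" else intron[0]

    def donor_exon(self, intron: Tuple[int, int]) -> Tuple[int, int]:
        return self.left_exon[intron] if self.strand == "+" else self.right_exon[intron]

    def acceptor_exon(self, intron: Tuple[int, int]) -> Tuple[int, int]:
        return self.right_exon[intron] if self.strand == "+" else self.left_exon[intron]


def _add(
    events: Dict[Tuple[str, Tuple[int, ...]], ASEvent],
    gene_id: str,
    etype: str,
    signature: Tuple[int, ...],
    inclusion: str,
    exclusion: str,
) -> None:
    key = (etype, signature)
    ev = events.get(key)
    if ev is None:
        ev = ASEvent(etype, gene_id, signature)
        events[key] = ev
    ev.inclusion_transcripts.add(inclusion)
    ev.exclusion_transcripts.add(exclusion)


def _pair_events(
    events: Dict[Tuple[str, Tuple[int, ...]], ASEvent],
    gene_id: str,
    a: _TxView,
    b: _TxView,
) -> None:
    strand = a.strand
    for inc, exc in ((a, b), (b, a)):
        # SE: internal exon of `inc` flanked by introns whose outer sites form
        # a single intron of `exc`.
        for i in range(1, len(inc.exons) - 1):
            es, ee = inc.exons[i]
            left, right = inc.introns[i - 1], inc.introns[i]
            skip = (left[0], right[1])
            if skip in exc.intron_set:
                _add(events, gene_id, "SE", (left[0], es, ee, right[1]), inc.id, exc.id)
        # RI: `inc` retains an intron of `exc` inside one exon with matching
        # outer boundaries.  Inclusion = the retaining transcript.
        for j, intron in enumerate(exc.introns):
            xs, xe = exc.exons[j]
            ys, ye = exc.exons[j + 1]
            if (xs, ye) in inc.exon_set:
                _add(events, gene_id, "RI", (xs, xe, ys, ye), inc.id, exc.id)

    # shared-site intron pairs
    for i1 in a.introns:
        for i2 in b.introns:
            if i1 == i2:
                continue
            d1, d2 = a.donor(i1), b.donor(i2)
            c1, c2 = a.acceptor(i1), b.acceptor(i2)
            if c1 == c2 and d1 != d2:
                e1, e2 = a.donor_exon(i1), b.donor_exon(i2)
                if _intervals_overlap(e1, e2):
                    sig = (min(d1, d2), max(d1, d2), c1)
                    # inclusion = the isoform keeping more exonic sequence,
                    # i.e. the shorter intron
                    inc, exc = (a, b) if (i1[1] - i1[0]) < (i2[1] - i2[0]) else (b, a)
                    _add(events, gene_id, "A5", sig, inc.id, exc.id)
                elif e1 == a.first_exon and e2 == b.first_exon:
                    lo, hi = sorted((e1, e2))
                    sig = lo + hi + (c1,)
                    # inclusion = the isoform whose first exon is more 5'
                    if strand == "+":
                        inc, exc = (a, b) if e1[0] < e2[0] else (b, a)
                    else:
                        inc, exc = (a, b) if e1[1] > e2[1] else (b, a)
                    _add(events, gene_id, "AF", sig, inc.id, exc.id)
            elif d1 == d2 and c1 != c2:
                e1, e2 = a.acceptor_exon(i1), b.acceptor_exon(i2)
                if _intervals_overlap(e1, e2):
                    sig = (d1, min(c1, c2), max(c1, c2))
                    inc, exc = (a, b) if (i1[1] - i1[0]) < (i2[1] - i2[0]) else (b, a)
                    _add(events, gene_id, "A3", sig, inc.id, exc.id)
                elif e1 == a.last_exon and e2 == b.last_exon:
                    lo, hi = sorted((e1, e2))
                    sig = (d1,) + lo + hi
                    # inclusion = the isoform whose last exon is more 3'
                    if strand == "+":
                        inc, exc = (a, b) if e1[1] > e2[1] else (b, a)
                    else:
                        inc, exc = (a, b) if e1[0] < e2[0] else (b, a)
                    _add(events, gene_id, "AL", sig, inc.id, exc.id)

    # MX: internal exons X (in a only) and Y (in b only), non-overlapping,
    # with identical flanking donor and acceptor splice sites.
    for ta, tb in ((a, b), (b, a)):
        for i in range(1, len(ta.exons) - 1):
            x = ta.exons[i]
            if x in tb.exon_set:
                continue
            dx, ax = ta.introns[i - 1][0], ta.introns[i][1]
            for j in range(1, len(tb.exons) - 1):
                y = tb.exons[j]
                if y in ta.exon_set or _intervals_overlap(x, y):
                    continue
                dy, ay = tb.introns[j - 1][0], tb.introns[j][1]
                if dx == dy and ax == ay:
                    first, second = sorted((x, y))
                    sig = (dx,) + first + second + (ax,)
                    upstream_tx = ta if x < y else tb
                    down_tx = tb if x < y else ta
                    if strand == "-":
                        upstream_tx, down_tx = down_tx, upstream_tx
                    _add(events, gene_id, "MX", sig, upstream_tx.id, down_tx.id)


def enumerate_events(gene: GeneModel) -> List[ASEvent]:
    """All deduplicated local AS events among the gene's isoform pairs."""
    events: Dict[Tuple[str, Tuple[int, ...]], ASEvent] = {}
    views = [_TxView(t) for t in gene.transcripts]
    for i in range(len(views)):
        for j in range(i + 1, len(views)):
            _pair_events(events, gene.gene_id, views[i], views[j])
    return [events[k] for k in sorted(events)]


def count_genes_with_events(ann: GenomeAnnotation) -> Dict[str, int]:
    """Per event type, the number of genes with at least one such event."""
    counts = {t: 0 for t in EVENT_TYPES}
    for gene in ann.genes.values():
        types_here = {ev.event_type for ev in enumerate_events(gene)}
        for t in types_here:
            counts[t] += 1
    return counts


def filter_retained_introns(
    ann: GenomeAnnotation, coverage: Mapping[str, float]
) -> Tuple[GenomeAnnotation, List[RIFilterDecision]]:
    """Drop retained-intron isoforms whose intron-spliced partner has strictly
    higher homology query coverage.

    The partner is the highest-coverage spliced form among the RI event's
    exclusion transcripts.  Missing coverage entries skip the decision with a
    warning; a gene is never emptied.
    """
    decisions: List[RIFilterDecision] = []
    new_genes: Dict[str, GeneModel] = {}
    for gid in ann.genes:
        gene = ann.genes[gid]
        ri_partners: Dict[str, Set[str]] = {}
        for ev in enumerate_events(gene):
            if ev.event_type != "RI":
                continue
            for tid in ev.inclusion_transcripts:
                ri_partners.setdefault(tid, set()).update(ev.exclusion_transcripts)
        to_remove: Set[str] = set()
        gene_decisions: List[RIFilterDecision] = []
        for tid in sorted(ri_partners):
            partners = sorted(
                (p for p in ri_partners[tid] if p in coverage),
                key=lambda p: (-coverage[p], p),
            )
            if tid not in coverage or not partners:
                log.warning(
                    "retained-intron filter: missing coverage for %s; kept", tid
                )
                continue
            partner = partners[0]
            removed = coverage[partner] > coverage[tid]
            gene_decisions.append(
                RIFilterDecision(
                    ri_transcript_id=tid,
                    no_ri_transcript_id=partner,
                    coverage_with_ri=coverage[tid],
                    coverage_without_ri=coverage[partner],
                    removed=removed,
                )
            )
            if removed:
                to_remove.add(tid)
        if to_remove and len(to_remove) == len(gene.transcripts):
            # keep the highest-coverage isoform rather than emptying the gene
            keep = max(
                to_remove, key=lambda t: (coverage.get(t, float("-inf")), t)
            )
            to_remove.discard(keep)
            gene_decisions = [
                replace(d, removed=False, kept_to_preserve_gene=True)
                if d.ri_transcript_id == keep
                else d
                for d in gene_decisions
            ]
        decisions.extend(gene_decisions)
        kept = [t for t in gene.transcripts if t.transcript_id not in to_remove]
        new_genes[gid] = GeneModel(gid, kept, biotype=gene.biotype)
    return (
        GenomeAnnotation(genes=new_genes, source_label=ann.source_label),
        decisions,
    )
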