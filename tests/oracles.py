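"""Independent brute-force oracles used to check the production code.

The splicing-event oracle works in transcript-oriented coordinates (minus
strand mirrored through negation) so transcription always runs left to
right; the production implementation works strand-conditionally in genomic
coordinates.  Both must produce identical event sets.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from annoforge.models import GeneModel


def exonic_union_length_oracle(gene: GeneModel) -> int:
    """Per-base boolean membership count."""
    lo = min(e.start for t in gene.transcripts for e in t.exons)
    hi = max(e.end for t in gene.transcripts for e in t.exons)
    covered = np.zeros(hi - lo, dtype=bool)
    for t in gene.transcripts:
        for e in t.exons:
            covered[e.start - lo : e.end - lo] = True
    return int(covered.sum())


def coverage_oracle(reads, lo: int, hi: int) -> np.ndarray:
    """Dense per-base increment coverage over [lo, hi)."""
    cov = np.zeros(hi - lo, dtype=int)
    for r in reads:
        cov[max(r.start, lo) - lo : min(r.end, hi) - lo] += 1
    return cov


# ------------------------------------------------------------- AS events

Event = Tuple[str, Tuple[int, ...], FrozenSet[str], FrozenSet[str]]


def _orient(t) -> List[Tuple[int, int]]:
    """Exons in transcript order; minus strand mirrored via negation."""
    if t.strand == "+":
        return [(e.start, e.end) for e in t.exons]
    return [(-e.end, -e.start) for e in reversed(t.exons)]


def _g(pos: int, strand: str) -> int:
    return pos if strand == "+" else -pos


def enumerate_events_oracle(gene: GeneModel) -> Set[Event]:
    """Literal pairwise application of the seven event definitions."""
    strand = gene.strand
    txs = [(t.transcript_id, _orient(t)) for t in gene.transcripts]
    merged: Dict[Tuple[str, Tuple[int, ...]], Tuple[Set[str], Set[str]]] = defaultdict(
        lambda: (set(), set())
    )

    def emit(etype: str, sig: Tuple[int, ...], inc: str, exc: str) -> None:
        merged[(etype, sig)][0].add(inc)
        merged[(etype, sig)][1].add(exc)

    def introns(exons):
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]

    for ia in range(len(txs)):
        for ib in range(len(txs)):
            if ia == ib:
                continue
            aid, aex = txs[ia]
            bid, bex = txs[ib]
            ain, bin_ = introns(aex), introns(bex)

            # SE: internal exon of a, with b joining the flanks directly
            for k in range(1, len(aex) - 1):
                d = ain[k - 1][0]
                acc = ain[k][1]
                if (d, acc) in bin_:
                    sig = tuple(
                        sorted(
                            _g(x, strand)
                            for x in (d, aex[k][0], aex[k][1], acc)
                        )
                    )
                    emit("SE", sig, aid, bid)

            # RI: a has one exon spanning exactly two consecutive exons of b
            for k in range(len(bex) - 1):
                span = (bex[k][0], bex[k + 1][1])
                if span in aex:
                    sig = tuple(
                        sorted(
                            _g(x, strand)
                            for x in (bex[k][0], bex[k][1], bex[k + 1][0], bex[k + 1][1])
                        )
                    )
                    emit("RI", sig, aid, bid)

            if ia < ib:
                # shared-site intron pairs
                for i1 in ain:
                    e1 = next(e for e in aex if e[1] == i1[0])
                    f1 = next(e for e in aex if e[0] == i1[1])
                    for i2 in bin_:
                        if i1 == i2:
                            continue
                        e2 = next(e for e in bex if e[1] == i2[0])
                        f2 = next(e for e in bex if e[0] == i2[1])
                        if i1[1] == i2[1] and i1[0] != i2[0]:
                            # same acceptor, different donor
                            gd = sorted((_g(i1[0], strand), _g(i2[0], strand)))
                            ga = _g(i1[1], strand)
                            if e1[0] < e2[1] and e2[0] < e1[1]:
                                inc, exc = (
                                    (aid, bid)
                                    if i1[1] - i1[0] < i2[1] - i2[0]
                                    else (bid, aid)
                                )
                                emit("A5", (gd[0], gd[1], ga), inc, exc)
                            elif e1 == aex[0] and e2 == bex[0]:
                                ge1 = tuple(sorted(_g(x, strand) for x in e1))
                                ge2 = tuple(sorted(_g(x, strand) for x in e2))
                                lo, hi = sorted((ge1, ge2))
                                inc, exc = (aid, bid) if e1[0] < e2[0] else (bid, aid)
                                emit("AF", lo + hi + (ga,), inc, exc)
                        if i1[0] == i2[0] and i1[1] != i2[1]:
                            # same donor, different acceptor
                            gc = sorted((_g(i1[1], strand), _g(i2[1], strand)))
                            gdon = _g(i1[0], strand)
                            if f1[0] < f2[1] and f2[0] < f1[1]:
                                inc, exc = (
                                    (aid, bid)
                                    if i1[1] - i1[0] < i2[1] - i2[0]
                                    else (bid, aid)
                                )
                                emit("A3", (gdon, gc[0], gc[1]), inc, exc)
                            elif f1 == aex[-1] and f2 == bex[-1]:
                                gf1 = tuple(sorted(_g(x, strand) for x in f1))
                                gf2 = tuple(sorted(_g(x, strand) for x in f2))
                                lo, hi = sorted((gf1, gf2))
                                inc, exc = (aid, bid) if f1[1] > f2[1] else (bid, aid)
                                emit("AL", (gdon,) + lo + hi, inc, exc)

                # MX: internal exons x (only in a) and y (only in b) with the
                # same outer flanking splice sites, non-overlapping
                for k in range(1, len(aex) - 1):
                    x = aex[k]
                    if x in bex:
                        continue
                    for m in range(1, len(bex) - 1):
                        y = bex[m]
                        if y in aex or (x[0] < y[1] and y[0] < x[1]):
                            continue
                        if (
                            ain[k - 1][0] == bin_[m - 1][0]
                            and ain[k][1] == bin_[m][1]
                        ):
                            coords = (
                                ain[k - 1][0],
                                x[0], x[1], y[0], y[1],
                                ain[k][1],
                            )
                            sig = tuple(sorted(_g(c, strand) for c in coords))
                            inc, exc = (aid, bid) if x[0] < y[0] else (bid, aid)
                            emit("MX", sig, inc, exc)

    return {
        (etype, sig, frozenset(inc), frozenset(exc))
        for (etype, sig), (inc, exc) in merged.items()
    }
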