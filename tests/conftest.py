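from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pytest

from annoforge.models import (
    Exon,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)


def make_tx(
    tid: str,
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    gene_id: str = "g1",
    cds: Sequence[Tuple[int, int]] | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        tid,
        gene_id,
        [Exon(GenomicInterval(chrom, s, e, strand)) for s, e in exons],
        cds=[GenomicInterval(chrom, s, e, strand) for s, e in cds] if cds else None,
    )


def make_gene(
    gid: str,
    isoforms: Sequence[Sequence[Tuple[int, int]]],
    strand: str = "+",
    chrom: str = "chr1",
    biotype: str = "other",
) -> GeneModel:
    return GeneModel(
        gid,
        [
            make_tx(f"{gid}.t{i + 1}", exons, strand, chrom, gid)
            for i, exons in enumerate(isoforms)
        ],
        biotype=biotype,
    )


def make_annotation(genes: Sequence[GeneModel], label: str = "") -> GenomeAnnotation:
    return GenomeAnnotation(genes={g.gene_id: g for g in genes}, source_label=label)


def random_toy_gene(rng: np.random.Generator, gid: str = "g") -> GeneModel:
    """Messy random gene: a shared exon skeleton with 2-4 isoforms derived by
    subsetting, boundary shifts, and exon fusions (retained introns)."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_skel = int(rng.integers(3, 9))
    pos = int(rng.integers(0, 1000))
    skeleton: List[Tuple[int, int]] = []
    for _ in range(n_skel):
        length = int(rng.integers(30, 120))
        skeleton.append((pos, pos + length))
        pos += length + int(rng.integers(40, 200))

    def one_isoform(tid: str) -> TranscriptModel | None:
        keep = sorted(
            rng.choice(n_skel, size=int(rng.integers(1, n_skel + 1)), replace=False)
        )
        exons = [list(skeleton[k]) for k in keep]
        # random boundary shifts into the flanking gaps
        for i, ex in enumerate(exons):
            if rng.random() < 0.3:
                left_gap = ex[0] - (exons[i - 1][1] if i else ex[0] - 30)
                if left_gap > 2:
                    ex[0] -= int(rng.integers(1, min(left_gap - 1, 25)))
            if rng.random() < 0.3:
                right_gap = (
                    exons[i + 1][0] if i + 1 < len(exons) else ex[1] + 30
                ) - ex[1]
                if right_gap > 2:
                    ex[1] += int(rng.integers(1, min(right_gap - 1, 25)))
        # random fusion of one adjacent pair (retained intron)
        if len(exons) > 1 and rng.random() < 0.3:
            i = int(rng.integers(0, len(exons) - 1))
            exons[i] = [exons[i][0], exons[i + 1][1]]
            del exons[i + 1]
        try:
            return make_tx(tid, [tuple(e) for e in exons], strand, gene_id=gid)
        except ValidationError:
            return None

    isoforms: List[TranscriptModel] = []
    want = int(rng.integers(2, 5))
    attempts = 0
    while len(isoforms) < want and attempts < 50:
        t = one_isoform(f"{gid}.t{len(isoforms) + 1}")
        attempts += 1
        if t is not None:
            isoforms.append(t)
    if len(isoforms) < 2:
        return random_toy_gene(rng, gid)
    return GeneModel(gid, isoforms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
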