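"""Synthetic data with planted ground truth for every pipeline input.

Everything the pipeline consumes can be generated here with a fixed seed and
a machine-readable truth ledger: an old/new annotation pair with planted
boundary extensions, gene merges, novel genes and splicing events; dT/hex
read sets around true TTSs and internal A-stretches; isoform abundance
matrices with planted proportion shifts; and UMI matrices with planted
cluster markers and condition-biased genes.

Background (non-event) genes carry a single isoform, so the ledger's planted
event list is exactly the splicing-event content of the emitted annotation
and recovery can be asserted without slack.  Default parameters emulate the
shape of the real comparison at desk scale: a few hundred genes, extension
categories dominated by TTS growth, lognormal extension lengths with medians
251 nt (TTS) and 31 nt (TSS), and a small merged/novel gene contingent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dtu import IsoformAbundance
from .models import (
    Exon,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
)
from .dtseq import AlignedFirstMate
from .scquant import CountMatrix

EXT_CATEGORY_PROBS = {
    "no_change": 0.45,
    "tss_extended": 0.12,
    "tts_extended": 0.30,
    "both_extended": 0.08,
    "contracted": 0.05,
}


@dataclass
class SimParams:
    seed: int = 0
    # annotation skeleton
    n_genes: int = 500
    exons_per_gene: Tuple[int, int] = (1, 8)
    exon_length_range: Tuple[int, int] = (80, 300)
    intron_length_range: Tuple[int, int] = (200, 1500)
    intergenic_gap_range: Tuple[int, int] = (5000, 10000)
    genes_per_chrom: int = 100
    # boundary changes
    category_probs: Dict[str, float] = field(
        default_factory=lambda: dict(EXT_CATEGORY_PROBS)
    )
    tss_extension_median: float = 31.0
    tts_extension_median: float = 251.0
    extension_sigma: float = 0.8
    max_extension: int = 2000
    contraction_median: float = 20.0
    # structural changes
    n_merged_pairs: int = 5
    n_novel_genes: int = 12
    events_per_type: Dict[str, int] = field(
        default_factory=lambda: {t: 8 for t in ("SE", "MX", "A5", "A3", "RI", "AF", "AL")}
    )
    # dT/hex reads
    read_length: int = 75
    dt_reads_per_tts: int = 20
    hex_reads_per_transcript: int = 60
    hex_terminal_reads: int = 2
    hex_end_gap: int = 40  # hex inserts priming closer to the tail fail size selection
    summit_jitter_sd: float = 20.0
    n_internal_a_stretches: int = 50
    a_stretch_dt_reads: int = 20
    a_stretch_hex_boost: int = 80
    # DTU
    n_dtu_genes: int = 20
    dprop_shift: float = 0.6
    n_replicates: int = 3
    replicate_concentration: float = 300.0
    gene_tpm_median: float = 50.0
    gene_tpm_sigma: float = 1.0
    # single cell
    n_cell_genes: int = 1000
    n_clusters: int = 4
    cells_per_cluster: int = 200
    n_samples_per_condition: int = 2
    markers_per_cluster: int = 10
    marker_fold_change: float = 8.0
    marker_detection: float = 0.4
    n_de_genes: int = 10
    de_fold_change: float = 4.0
    de_detection: float = 0.5
    nb_dispersion: float = 2.0     # NB size parameter r
    baseline_mean_log_sd: float = 1.0
    depth_log_sd: float = 0.3

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthLedger:
    """Planted facts about the emitted data, exactly as generated."""

    transcripts: Dict[str, Dict] = field(default_factory=dict)
    merges: Dict[str, List[str]] = field(default_factory=dict)
    novel_genes: List[str] = field(default_factory=list)
    lost_genes: List[str] = field(default_factory=list)
    events: Dict[str, List[Dict]] = field(default_factory=dict)
    tts_sites: List[Dict] = field(default_factory=list)
    a_stretch_sites: List[Dict] = field(default_factory=list)
    dtu: Dict[str, Dict] = field(default_factory=dict)
    markers: Dict[str, Dict] = field(default_factory=dict)
    de_genes: Dict[str, Dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------- annotation


def _random_transcript(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    start: int,
    n_exons: int,
    p: SimParams,
    gene_id: str,
    transcript_id: str,
) -> TranscriptModel:
    exons: List[Exon] = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(*p.exon_length_range))
        exons.append(Exon(GenomicInterval(chrom, pos, pos + length, strand)))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(*p.intron_length_range))
    return TranscriptModel(transcript_id, gene_id, exons)


def _shift_outer(
    t: TranscriptModel, tss_delta: int, tts_delta: int, new_tid: Optional[str] = None
) -> TranscriptModel:
    """Move the outer boundaries outward by the signed strand-aware deltas."""
    exons = [(e.start, e.end) for e in t.exons]
    if t.strand == "+":
        exons[0] = (exons[0][0] - tss_delta, exons[0][1])
        exons[-1] = (exons[-1][0], exons[-1][1] + tts_delta)
    else:
        exons[-1] = (exons[-1][0], exons[-1][1] + tss_delta)
        exons[0] = (exons[0][0] - tts_delta, exons[0][1])
    return TranscriptModel(
        new_tid or t.transcript_id,
        t.gene_id,
        [Exon(GenomicInterval(t.chrom, s, e, t.strand)) for s, e in exons],
    )


def _clone(t: TranscriptModel, tid: str) -> TranscriptModel:
    return TranscriptModel(tid, t.gene_id, list(t.exons), cds=t.cds)


def _lognormal_int(rng, median: float, sigma: float, lo: int, hi: int) -> int:
    val = int(round(rng.lognormal(np.log(median), sigma)))
    return int(min(max(val, lo), hi))


def _event_partner(
    rng: np.random.Generator, t: TranscriptModel, etype: str, p: SimParams
) -> Tuple[TranscriptModel, Dict]:
    """Build the second isoform realizing one local event against ``t``.

    Assumes ``t`` has the exon count the event type needs (SE >=3, MX >=4
    with only 3 used per isoform, others >=2).
    """
    chrom, strand = t.chrom, t.strand
    exons = [(e.start, e.end) for e in t.exons]
    tid = t.transcript_id + ".alt"

    def build(coords: Sequence[Tuple[int, int]]) -> TranscriptModel:
        return TranscriptModel(
            tid,
            t.gene_id,
            [Exon(GenomicInterval(chrom, s, e, strand)) for s, e in coords],
        )

    if etype == "SE":
        i = int(rng.integers(1, len(exons) - 1))
        partner = build(exons[:i] + exons[i + 1 :])
        detail = {"inclusion": t.transcript_id, "exclusion": tid, "exon": exons[i]}
    elif etype == "RI":
        i = int(rng.integers(0, len(exons) - 1))
        fused = (exons[i][0], exons[i + 1][1])
        partner = build(exons[:i] + [fused] + exons[i + 2 :])
        detail = {"inclusion": tid, "exclusion": t.transcript_id,
                  "intron": (exons[i][1], exons[i + 1][0])}
    elif etype in ("A5", "A3"):
        # move the strand-aware donor (A5) or acceptor (A3) of one intron
        i = int(rng.integers(0, len(exons) - 1))
        gap = exons[i + 1][0] - exons[i][1]
        delta = int(rng.integers(20, max(21, gap - 20)))
        move_left_exon_end = (strand == "+") == (etype == "A5")
        mod = list(exons)
        if move_left_exon_end:
            mod[i] = (mod[i][0], mod[i][1] + delta)
        else:
            mod[i + 1] = (mod[i + 1][0] - delta, mod[i + 1][1])
        partner = build(mod)
        detail = {"inclusion": tid, "exclusion": t.transcript_id, "delta": delta}
    elif etype == "AF":
        # alternative first exon placed inside the first (strand-aware) intron
        first_genomic = 0 if strand == "+" else len(exons) - 2
        intron = (exons[first_genomic][1], exons[first_genomic + 1][0])
        mid = (intron[0] + intron[1]) // 2
        alt = (mid - 40, mid + 40)
        if strand == "+":
            partner = build([alt] + exons[1:])
        else:
            partner = build(exons[:-1] + [alt])
        detail = {"alt_first_exon": alt}
    elif etype == "AL":
        last_genomic = len(exons) - 2 if strand == "+" else 0
        intron = (exons[last_genomic][1], exons[last_genomic + 1][0])
        mid = (intron[0] + intron[1]) // 2
        alt = (mid - 40, mid + 40)
        if strand == "+":
            partner = build(exons[:-1] + [alt])
        else:
            partner = build([alt] + exons[1:])
        detail = {"alt_last_exon": alt}
    else:
        raise ValueError(f"unknown event type {etype}")
    detail["type"] = etype
    detail["partner"] = tid
    detail["base"] = t.transcript_id
    return partner, detail


_MIN_EXONS = {"SE": 3, "MX": 4, "RI": 2, "A5": 2, "A3": 2, "AF": 2, "AL": 2}


def generate_annotation_pair(
    p: SimParams,
) -> Tuple[GenomeAnnotation, GenomeAnnotation, TruthLedger]:
    """Old/new annotation pair with planted modifications and a truth ledger.

    Deterministic under ``p.seed``; the new annotation differs from the old
    by boundary changes, added event isoforms, gene merges and novel genes,
    with internal boundaries of matched transcripts untouched.
    """
    rng = p.rng()
    truth = TruthLedger()

    event_plan: List[str] = []
    for etype in sorted(p.events_per_type):
        event_plan.extend([etype] * p.events_per_type[etype])
    n_events = len(event_plan)
    if p.n_genes < n_events + 2 * p.n_merged_pairs + 10:
        raise ValueError("n_genes too small for the requested planted features")

    # lay out single-isoform genes left to right per chromosome
    old_genes: Dict[str, GeneModel] = {}
    order: List[str] = []
    pos = 10_000
    chrom_i = 0
    for gi in range(p.n_genes):
        if gi % p.genes_per_chrom == 0 and gi:
            chrom_i += 1
            pos = 10_000
        chrom = f"chr{chrom_i + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{gi:05d}"
        need = _MIN_EXONS[event_plan[gi]] if gi < n_events else None
        lo, hi = p.exons_per_gene
        n_exons = int(rng.integers(max(lo, need or lo), hi + 1))
        t = _random_transcript(rng, chrom, strand, pos, n_exons, p, gid, gid + ".t1")
        old_genes[gid] = GeneModel(gid, [t])
        order.append(gid)
        pos = t.span_end + int(rng.integers(*p.intergenic_gap_range))

    gids = list(order)
    event_gids = gids[:n_events]
    merge_gids: List[Tuple[str, str]] = []
    cursor = n_events
    # merged pairs must be adjacent on the same chromosome; force same strand
    while len(merge_gids) < p.n_merged_pairs:
        a, b = gids[cursor], gids[cursor + 1]
        ga, gb = old_genes[a], old_genes[b]
        if ga.chrom == gb.chrom:
            if ga.strand != gb.strand:
                # re-strand b to match a (before any reads/derived use)
                tb = old_genes[b].transcripts[0]
                old_genes[b] = GeneModel(
                    b,
                    [
                        TranscriptModel(
                            tb.transcript_id,
                            b,
                            [
                                Exon(
                                    GenomicInterval(
                                        e.interval.chrom,
                                        e.start,
                                        e.end,
                                        ga.strand,
                                    )
                                )
                                for e in tb.exons
                            ],
                        )
                    ],
                )
            merge_gids.append((a, b))
            cursor += 2
        else:
            cursor += 1
    plain_gids = [
        g
        for g in gids[n_events:]
        if g not in {x for pair in merge_gids for x in pair}
    ]

    # new annotation
    new_genes: Dict[str, GeneModel] = {}

    cats = list(p.category_probs)
    probs = np.array([p.category_probs[c] for c in cats])
    probs = probs / probs.sum()
    for gid in plain_gids:
        t = old_genes[gid].transcripts[0]
        cat = str(rng.choice(cats, p=probs))
        tss_d = tts_d = 0
        if cat in ("tss_extended", "both_extended"):
            tss_d = _lognormal_int(
                rng, p.tss_extension_median, p.extension_sigma, 1, p.max_extension
            )
        if cat in ("tts_extended", "both_extended"):
            tts_d = _lognormal_int(
                rng, p.tts_extension_median, p.extension_sigma, 1, p.max_extension
            )
        if cat == "contracted":
            side = "tts" if rng.random() < 0.7 else "tss"
            exon = t.exons[-1] if (t.strand == "+") == (side == "tts") else t.exons[0]
            shrink = _lognormal_int(
                rng, p.contraction_median, 0.6, 1, max(1, len(exon.interval) - 10)
            )
            if side == "tts":
                tts_d = -shrink
            else:
                tss_d = -shrink
        new_genes[gid] = GeneModel(
            gid, [_shift_outer(t, tss_d, tts_d)], biotype=old_genes[gid].biotype
        )
        truth.transcripts[t.transcript_id] = {
            "category": cat,
            "tss_delta": tss_d,
            "tts_delta": tts_d,
        }

    for gid, etype in zip(event_gids, event_plan):
        base = old_genes[gid].transcripts[0]
        if etype == "MX":
            # from the exon skeleton e0..e3(+tail): base keeps e1, partner
            # keeps e2; both share the flanking donor (e0) and acceptor (e3)
            ex = [(e.start, e.end) for e in base.exons]
            chrom, strand = base.chrom, base.strand

            def _mx_build(tid: str, coords) -> TranscriptModel:
                return TranscriptModel(
                    tid,
                    gid,
                    [Exon(GenomicInterval(chrom, s, e, strand)) for s, e in coords],
                )

            base = _mx_build(base.transcript_id, [ex[0], ex[1], ex[3]] + ex[4:])
            old_genes[gid] = GeneModel(gid, [base])
            partner = _mx_build(
                base.transcript_id + ".alt", [ex[0], ex[2], ex[3]] + ex[4:]
            )
            detail = {
                "type": "MX",
                "partner": partner.transcript_id,
                "base": base.transcript_id,
                "exon_a": ex[1],
                "exon_b": ex[2],
            }
        else:
            partner, detail = _event_partner(rng, base, etype, p)
        new_genes[gid] = GeneModel(gid, [_clone(base, base.transcript_id), partner])
        truth.events.setdefault(gid, []).append(detail)
        truth.transcripts[base.transcript_id] = {
            "category": "no_change",
            "tss_delta": 0,
            "tts_delta": 0,
        }

    for mi, (a, b) in enumerate(merge_gids):
        ta = old_genes[a].transcripts[0]
        tb = old_genes[b].transcripts[0]
        mid = f"M{mi:03d}"
        bridge = TranscriptModel(
            mid + ".t1",
            mid,
            [Exon(e.interval) for e in ta.exons] + [Exon(e.interval) for e in tb.exons],
        )
        new_genes[mid] = GeneModel(mid, [bridge])
        truth.merges[mid] = sorted([a, b])

    last_ends = {}
    for g in old_genes.values():
        last_ends[g.chrom] = max(last_ends.get(g.chrom, 0), g.span_end)
    pos = max(last_ends.values()) + 50_000
    for ni in range(p.n_novel_genes):
        gid = f"N{ni:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        t = _random_transcript(
            rng, "chr1", strand, pos, int(rng.integers(1, 5)), p, gid, gid + ".t1"
        )
        new_genes[gid] = GeneModel(gid, [t])
        truth.novel_genes.append(gid)
        pos = t.span_end + int(rng.integers(*p.intergenic_gap_range))

    old = GenomeAnnotation(genes=old_genes, source_label="old")
    new = GenomeAnnotation(genes=new_genes, source_label="new")
    _self_check_pair(old, new, truth)
    return old, new, truth


def _self_check_pair(
    old: GenomeAnnotation, new: GenomeAnnotation, truth: TruthLedger
) -> None:
    """Internal consistency check: the ledger describes the emitted pair."""
    new_tx = new.transcript_index()
    old_tx = old.transcript_index()
    for tid, fact in truth.transcripts.items():
        assert tid in old_tx and tid in new_tx
        o, n = old_tx[tid], new_tx[tid]
        assert o.intron_chain == n.intron_chain, tid
    for mid, parents in truth.merges.items():
        assert mid in new.genes
        assert all(g in old.genes for g in parents)
    for gid in truth.novel_genes:
        assert gid in new.genes and gid not in old.genes


# ---------------------------------------------------------------- dT / hex


def simulate_dthex_reads(
    ann: GenomeAnnotation, p: SimParams
) -> Tuple[List[AlignedFirstMate], List[AlignedFirstMate], TruthLedger]:
    """dT and hex first-mate read sets around true TTSs and planted internal
    A-stretches.

    Reads are placed on the genomic span of each transcript (splicing is not
    modelled).  Hexamer reads sample the body uniformly and never extend past
    the TTS; dT reads end at the TTS plus Gaussian jitter.  Each A-stretch
    site gets a dT pile ending at the site plus a strong hexamer pile
    overlapping it and continuing downstream — the signature the peak
    categorization is designed to discard.
    """
    if p.summit_jitter_sd < 0:
        raise ValueError("summit jitter sigma must be >= 0")
    rng = p.rng()
    truth = TruthLedger()
    L = p.read_length
    dt_reads: List[AlignedFirstMate] = []
    hex_reads: List[AlignedFirstMate] = []

    eligible: List[TranscriptModel] = []
    for gid in sorted(ann.genes):
        for t in ann.genes[gid].transcripts:
            if t.span_end - t.span_start >= 5 * L:
                eligible.append(t)
    a_stretch_tx = set(
        t.transcript_id for t in eligible[: p.n_internal_a_stretches]
    )

    rid = 0
    for t in eligible:
        chrom, strand = t.chrom, t.strand
        span_s, span_e = t.span_start, t.span_end
        tts = t.tts
        truth.tts_sites.append(
            {"transcript_id": t.transcript_id, "chrom": chrom,
             "strand": strand, "pos": tts}
        )
        # dT reads: first mates ending at the polyA junction (+ jitter)
        jitter = np.round(
            rng.normal(0.0, p.summit_jitter_sd, size=p.dt_reads_per_tts)
        ).astype(int)
        for j in jitter:
            if strand == "+":
                end = tts + 1 + j
                dt_reads.append(
                    AlignedFirstMate(f"dt{rid}", chrom, end - L, end, strand, "dT")
                )
            else:
                start = tts - j
                dt_reads.append(
                    AlignedFirstMate(f"dt{rid}", chrom, start, start + L, strand, "dT")
                )
            rid += 1
        # hex reads: 5' ends uniform along the body.  Priming within
        # hex_end_gap of the polyA junction gives inserts too short for size
        # selection, so hex coverage stops short of the TTS.
        if strand == "+":
            lo, hi = span_s, span_e - L - p.hex_end_gap
        else:
            lo, hi = span_s + p.hex_end_gap, span_e - L
        starts = rng.integers(lo, hi + 1, size=p.hex_reads_per_transcript)
        for s in starts:
            hex_reads.append(
                AlignedFirstMate(f"hx{rid}", chrom, int(s), int(s) + L, strand, "hex")
            )
            rid += 1
        # terminal-fragment hex reads guarantee body signal abutting the TTS
        for _ in range(p.hex_terminal_reads):
            if strand == "+":
                end = tts + 1 - p.hex_end_gap
                hex_reads.append(
                    AlignedFirstMate(f"hx{rid}", chrom, end - L, end, strand, "hex")
                )
            else:
                start = tts + p.hex_end_gap
                hex_reads.append(
                    AlignedFirstMate(f"hx{rid}", chrom, start, start + L, strand, "hex")
                )
            rid += 1
        # internal A-stretch: dT pile at the site, hex pile continuing downstream
        if t.transcript_id in a_stretch_tx:
            if strand == "+":
                site = int(rng.integers(span_s + 2 * L, span_e - 2 * L))
                for _ in range(p.a_stretch_dt_reads):
                    dt_reads.append(
                        AlignedFirstMate(
                            f"dt{rid}", chrom, site + 1 - L, site + 1, strand, "dT"
                        )
                    )
                    rid += 1
                for _ in range(p.a_stretch_hex_boost):
                    hex_reads.append(
                        AlignedFirstMate(
                            f"hx{rid}", chrom, site - 5, site - 5 + L, strand, "hex"
                        )
                    )
                    rid += 1
            else:
                site = int(rng.integers(span_s + 2 * L, span_e - 2 * L))
                for _ in range(p.a_stretch_dt_reads):
                    dt_reads.append(
                        AlignedFirstMate(
                            f"dt{rid}", chrom, site, site + L, strand, "dT"
                        )
                    )
                    rid += 1
                for _ in range(p.a_stretch_hex_boost):
                    hex_reads.append(
                        AlignedFirstMate(
                            f"hx{rid}", chrom, site + 6 - L, site + 6, strand, "hex"
                        )
                    )
                    rid += 1
            truth.a_stretch_sites.append(
                {"transcript_id": t.transcript_id, "chrom": chrom,
                 "strand": strand, "pos": site}
            )
    return dt_reads, hex_reads, truth


# ---------------------------------------------------------------- DTU


def simulate_isoform_abundance(
    ann: GenomeAnnotation, p: SimParams
) -> Tuple[IsoformAbundance, TruthLedger]:
    """TPM-like abundances for multi-isoform genes with planted DTU.

    Per gene, isoform proportions come from a Dirichlet around a condition
    target; DTU genes swap a proportion mass of ``dprop_shift`` between their
    two most 5' isoforms across conditions.
    """
    rng = p.rng()
    truth = TruthLedger()
    multi = [g for g in sorted(ann.genes) if len(ann.genes[g].transcripts) >= 2]
    if p.n_dtu_genes > len(multi):
        raise ValueError("not enough multi-isoform genes for requested DTU count")
    dtu_set = set(multi[: p.n_dtu_genes])
    if not (0 < p.dprop_shift <= 0.8):
        raise ValueError("dprop_shift must be in (0, 0.8]")

    samples = [
        f"{cond}_{r + 1}" for cond in ("A", "B") for r in range(p.n_replicates)
    ]
    conditions = {s: s.split("_")[0] for s in samples}
    rows: Dict[str, List[float]] = {}
    tx2gene: Dict[str, str] = {}
    base_lo = (1 - p.dprop_shift) / 2  # e.g. 0.2 for a 0.6 shift

    for gid in multi:
        txs = ann.genes[gid].transcripts
        k = len(txs)
        for t in txs:
            tx2gene[t.transcript_id] = gid
        if gid in dtu_set:
            target = {
                "A": np.array([base_lo, 1 - base_lo] + [0.0] * (k - 2)),
                "B": np.array([1 - base_lo, base_lo] + [0.0] * (k - 2)),
            }
            # give any extra isoforms a small share, renormalized
            for c in target:
                if k > 2:
                    target[c] = np.where(target[c] == 0, 0.05, target[c])
                    target[c] = target[c] / target[c].sum()
        else:
            base = rng.dirichlet(np.full(k, 2.0))
            target = {"A": base, "B": base}
        expr = rng.lognormal(np.log(p.gene_tpm_median), p.gene_tpm_sigma)
        mat = np.zeros((k, len(samples)))
        for si, s in enumerate(samples):
            tgt = np.clip(target[conditions[s]], 1e-3, None)
            tgt = tgt / tgt.sum()
            props = rng.dirichlet(tgt * p.replicate_concentration)
            depth = rng.lognormal(0.0, 0.05)
            mat[:, si] = props * expr * depth
        for ti, t in enumerate(txs):
            rows[t.transcript_id] = mat[ti].tolist()
        truth.dtu[gid] = {
            "dtu": gid in dtu_set,
            "delta": p.dprop_shift if gid in dtu_set else 0.0,
        }

    ab = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return IsoformAbundance(ab, tx2gene, conditions), truth


# ---------------------------------------------------------------- UMI matrix


def _nb_mean_for_detection(detection: float, r: float) -> float:
    """NB mean with size r such that P(X > 0) equals ``detection``."""
    return r * ((1 - detection) ** (-1.0 / r) - 1.0)


def simulate_umi_matrix(
    p: SimParams,
) -> Tuple[CountMatrix, pd.DataFrame, TruthLedger]:
    """Negative-binomial UMI counts with planted cluster markers and
    condition-biased genes, heterogeneous cell depths, and sample labels."""
    rng = p.rng()
    truth = TruthLedger()
    G, K = p.n_cell_genes, p.n_clusters
    n_cells = K * p.cells_per_cluster
    r = p.nb_dispersion

    clusters = np.repeat(np.arange(K), p.cells_per_cluster)
    perm = rng.permutation(n_cells)
    clusters = clusters[perm]
    conditions = np.array(["worker", "gamergate"])[
        rng.integers(0, 2, size=n_cells)
    ]
    sample_ids = np.array(
        [
            f"{c}{rng.integers(1, p.n_samples_per_condition + 1)}"
            for c in np.where(conditions == "worker", "w", "g")
        ]
    )
    depth = rng.lognormal(0.0, p.depth_log_sd, size=n_cells)

    base_mean = rng.lognormal(0.0, p.baseline_mean_log_sd, size=G)
    means = np.tile(base_mean[:, None], (1, n_cells))

    marker_mu_in = _nb_mean_for_detection(p.marker_detection, r)
    marker_mu_out = marker_mu_in / p.marker_fold_change
    gi = 0
    for k in range(K):
        for _ in range(p.markers_per_cluster):
            gene = f"MK{gi:04d}"
            means[gi] = np.where(clusters == k, marker_mu_in, marker_mu_out)
            truth.markers[gene] = {
                "cluster": int(k),
                "fold": p.marker_fold_change,
                "detection": p.marker_detection,
            }
            gi += 1
    de_mu_hi = _nb_mean_for_detection(p.de_detection, r)
    de_mu_lo = de_mu_hi / p.de_fold_change
    for d in range(p.n_de_genes):
        gene = f"DE{d:04d}"
        means[gi] = np.where(conditions == "gamergate", de_mu_hi, de_mu_lo)
        truth.de_genes[gene] = {
            "fold": p.de_fold_change,
            "detection": p.de_detection,
            "up_in": "gamergate",
        }
        gi += 1

    gene_ids = (
        [f"MK{i:04d}" for i in range(K * p.markers_per_cluster)]
        + [f"DE{i:04d}" for i in range(p.n_de_genes)]
        + [f"BG{i:04d}" for i in range(G - gi)]
    )
    means = means * depth[None, :]
    # NB(mean mu, size r) as Gamma-Poisson
    lam = rng.gamma(shape=r, scale=means / r)
    counts = rng.poisson(lam)
    m = CountMatrix(sp.csr_matrix(counts), gene_ids, [f"cell{i:05d}" for i in range(n_cells)])
    meta = pd.DataFrame(
        {
            "sample": sample_ids,
            "cluster": [f"c{k}" for k in clusters],
            "condition": conditions,
        },
        index=m.barcodes,
    )
    return m, meta, truth
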