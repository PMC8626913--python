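"""Recovery metrics against a simulation truth ledger."""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

from .diff import TranscriptMatch
from .dtseq import Peak, PeakDecision
from .simulate import TruthLedger


def extension_recovery(
    matches: Sequence[TranscriptMatch], truth: TruthLedger
) -> Dict[str, float]:
    """Fraction of planted boundary changes recovered with exact category and
    exact signed deltas."""
    by_old = {m.old_id: m for m in matches}
    n = cat_ok = delta_ok = 0
    for tid, fact in truth.transcripts.items():
        m = by_old.get(tid)
        if m is None:
            n += 1
            continue
        n += 1
        if m.category == fact["category"]:
            cat_ok += 1
        if (
            m.extension is not None
            and m.extension.tss_delta == fact["tss_delta"]
            and m.extension.tts_delta == fact["tts_delta"]
        ):
            delta_ok += 1
    return {
        "n": n,
        "category_recovery": cat_ok / n if n else float("nan"),
        "delta_recovery": delta_ok / n if n else float("nan"),
    }


def merge_recovery(
    records, truth: TruthLedger
) -> Dict[str, float]:
    """Planted-merge sensitivity and the count of spurious merge calls."""
    found = {r.new_gene_id: set(r.old_gene_ids) for r in records}
    planted = {k: set(v) for k, v in truth.merges.items()}
    tp = sum(1 for k, v in planted.items() if found.get(k) == v)
    fp = sum(1 for k in found if k not in planted)
    return {
        "n_planted": len(planted),
        "n_detected": tp,
        "false_positives": fp,
        "sensitivity": tp / len(planted) if planted else float("nan"),
    }


def tts_recovery(
    decisions: Sequence[PeakDecision], truth: TruthLedger
) -> Dict[str, float]:
    """Sensitivity/precision of retained dT peaks against true TTS positions.

    A retained peak is a true positive iff its interval contains a true TTS
    on the same chrom and strand; a TTS is recovered iff some retained peak
    contains it.
    """
    retained: List[Peak] = [d.dt_peak for d in decisions if d.retained]
    sites = [(s["chrom"], s["strand"], s["pos"]) for s in truth.tts_sites]

    def contains(pk: Peak, site: Tuple[str, str, int]) -> bool:
        chrom, strand, pos = site
        return pk.chrom == chrom and pk.strand == strand and pk.start <= pos < pk.end

    recovered = sum(1 for s in sites if any(contains(pk, s) for pk in retained))
    true_peaks = sum(1 for pk in retained if any(contains(pk, s) for s in sites))
    sensitivity = recovered / len(sites) if sites else float("nan")
    precision = true_peaks / len(retained) if retained else float("nan")
    return {
        "n_sites": len(sites),
        "n_retained_peaks": len(retained),
        "sensitivity": sensitivity,
        "precision": precision,
    }


def marker_recovery(marker_stats, truth: TruthLedger) -> Dict[str, float]:
    """Sensitivity/precision of called markers against the planted marker set.

    A planted marker counts as recovered iff it is reported for its planted
    cluster; any called marker gene not planted for that group is a false
    positive.
    """
    called = {(s.gene, s.group) for s in marker_stats}
    planted = {(g, f"c{fact['cluster']}") for g, fact in truth.markers.items()}
    tp = len(called & planted)
    fp = len(called - planted)
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
    }
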