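"""Isoform proportions and the differential-transcript-usage (DTU) filter.

Proportions are computed per replicate from TPM-like abundances (transcript
abundance over its gene's total in that sample), then averaged within
condition.  The DTU statistics themselves (adjusted P, replication support)
are consumed as input; this module applies the published threshold filter:
padj < 1e-5, maxDprop > 0.5, rep_dtu_freq > 0.8, all strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd


@dataclass
class IsoformAbundance:
    """Transcript x sample abundance matrix with sample condition labels."""

    abundance: pd.DataFrame            # index: transcript_id, columns: samples
    tx2gene: Mapping[str, str]         # transcript_id -> gene_id
    conditions: Mapping[str, str]      # sample -> condition label

    def __post_init__(self) -> None:
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = set(self.abundance.index) - set(self.tx2gene)
        if missing:
            raise KeyError(
                f"transcripts absent from gene map: {sorted(missing)[:5]}"
            )


@dataclass
class Proportions:
    per_sample: pd.DataFrame       # transcript x sample, NaN where gene total 0
    condition_means: pd.DataFrame  # transcript x condition
    gene_ids: pd.Series            # transcript -> gene


def isoform_proportions(ab: IsoformAbundance) -> Proportions:
    """Per-sample isoform proportions and their unweighted condition means.

    Samples where a gene's total abundance is zero contribute no proportion
    for that gene (NaN) and are excluded from the condition mean.
    """
    genes = pd.Series({t: ab.tx2gene[t] for t in ab.abundance.index}, name="gene_id")
    totals = ab.abundance.groupby(genes).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        props = ab.abundance / totals
    props = props.where(totals > 0)
    cond = pd.Series(dict(ab.conditions))
    means = props.T.groupby(cond.reindex(props.columns)).mean().T
    return Proportions(per_sample=props, condition_means=means, gene_ids=genes)


def compute_max_dprop(
    props: Proportions, condition_pair: Tuple[str, str]
) -> pd.Series:
    """Per gene, the largest between-condition difference in mean isoform
    proportion.  Genes undefined in either condition are excluded."""
    a, b = condition_pair
    for c in (a, b):
        if c not in props.condition_means.columns:
            raise KeyError(f"condition {c!r} absent from proportions")
    diff = (props.condition_means[a] - props.condition_means[b]).abs()
    out: Dict[str, float] = {}
    for gene, sub in diff.groupby(props.gene_ids):
        if sub.isna().all():
            continue
        out[gene] = float(sub.max())
    return pd.Series(out, name="maxDprop").sort_index()


@dataclass
class DTUStats:
    gene_id: str
    padj: float
    maxDprop: float
    rep_dtu_freq: float


def filter_dtu(
    stats: Sequence[DTUStats] | pd.DataFrame,
    padj_max: float = 1e-5,
    dprop_min: float = 0.5,
    freq_min: float = 0.8,
) -> Set[str]:
    """Genes passing all three strict DTU thresholds."""
    if isinstance(stats, pd.DataFrame):
        rows = stats.itertuples()
        return {
            r.gene_id
            for r in rows
            if r.padj < padj_max and r.maxDprop > dprop_min and r.rep_dtu_freq > freq_min
        }
    return {
        s.gene_id
        for s in stats
        if s.padj < padj_max and s.maxDprop > dprop_min and s.rep_dtu_freq > freq_min
    }
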