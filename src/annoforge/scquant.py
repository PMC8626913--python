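"""Single-cell UMI matrix metrics: QC, log-normalization, detection
fractions, pseudobulk %UMI, and Wilcoxon marker / within-cluster DE calling.

The marker machinery mirrors the Seurat v3 conventions the analyses in this
field use: detection-fraction and log-fold-change pre-filters, a two-sided
Wilcoxon rank-sum test on log-normalized values, and Bonferroni adjustment.
The fold change is computed on back-transformed means,
``log((mean(expm1 x_in) + 1) / (mean(expm1 x_out) + 1))`` with natural log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Sparse UMI counts, genes x cells."""

    counts: sp.csr_matrix
    gene_ids: List[str]
    barcodes: List[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("matrix shape does not match gene/barcode lists")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("UMI counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError as exc:
            raise KeyError(f"gene {gene!r} not in matrix") from exc

    def subset(self, gene_mask: np.ndarray, cell_mask: np.ndarray) -> "CountMatrix":
        sub = self.counts[gene_mask][:, cell_mask]
        return CountMatrix(
            sub,
            [g for g, k in zip(self.gene_ids, gene_mask) if k],
            [b for b, k in zip(self.barcodes, cell_mask) if k],
        )


@dataclass
class QCParams:
    min_genes_per_cell: int = 200
    min_umis_per_cell: int = 500
    min_cells_per_gene: int = 3
    scale_factor: float = 10_000.0
    log_base: str = "e"  # "e" | "2"


@dataclass
class MarkerParams:
    only_pos: bool = True
    min_pct: float = 0.25
    logfc_threshold: float = 1.0
    padj_max: float = 0.05
    de_padj_max: float = 0.01
    mb_logfc_threshold: float = 1.5
    # within-cluster DE runs with the cited tool's defaults
    de_logfc_threshold: float = 0.25
    de_min_pct: float = 0.1
    bonferroni_all_genes: bool = False
    min_cells_per_group: int = 3


def qc_filter(m: CountMatrix, p: QCParams = QCParams()) -> CountMatrix:
    """Two-pass filter: genes detected in >= min_cells_per_gene cells of the
    raw matrix first, then cells with enough detected genes and total UMIs
    (both evaluated on the gene-filtered matrix)."""
    detected = (m.counts > 0)
    gene_mask = np.asarray(detected.sum(axis=1)).ravel() >= p.min_cells_per_gene
    genes_kept = m.counts[gene_mask]
    genes_per_cell = np.asarray((genes_kept > 0).sum(axis=0)).ravel()
    umis_per_cell = np.asarray(genes_kept.sum(axis=0)).ravel()
    cell_mask = (genes_per_cell >= p.min_genes_per_cell) & (
        umis_per_cell >= p.min_umis_per_cell
    )
    if not cell_mask.any():
        log.warning("qc_filter removed every cell")
    return m.subset(gene_mask, cell_mask)


@dataclass
class NormalizedMatrix:
    values: sp.csr_matrix  # genes x cells, log-normalized
    gene_ids: List[str]
    barcodes: List[str]
    log_base: str = "e"


def lognormalize(m: CountMatrix, p: QCParams = QCParams()) -> NormalizedMatrix:
    """value = log(1 + count / cell_total * scale_factor)."""
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cell; run qc_filter first")
    scaled = m.counts @ sp.diags(p.scale_factor / totals)
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    if p.log_base == "2":
        scaled.data /= math.log(2)
    return NormalizedMatrix(scaled, list(m.gene_ids), list(m.barcodes), p.log_base)


def detection_fraction(
    m: Union[CountMatrix, NormalizedMatrix],
    gene: str,
    cells: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of the given cells with > 0 UMI for the gene."""
    mat = m.counts if isinstance(m, CountMatrix) else m.values
    gi = m.gene_ids.index(gene)
    if cells is None:
        mask = np.ones(len(m.barcodes), dtype=bool)
    else:
        wanted = set(cells)
        mask = np.array([b in wanted for b in m.barcodes])
    if not mask.any():
        raise ValueError("empty cell subset: detection fraction undefined")
    row = np.asarray(mat[gi].todense()).ravel()[mask]
    return float((row > 0).mean())


def pseudobulk_percent_table(m: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Genes x (sample, cluster) table of pseudobulk %UMI.

    Each column: the gene's UMIs summed over that stratum's cells, as a
    percentage of all UMIs in the stratum.  Empty strata are omitted.
    """
    missing = set(m.barcodes) - set(meta.index)
    if missing:
        raise KeyError(f"cells without metadata: {sorted(missing)[:5]}")
    meta = meta.loc[m.barcodes]
    cols: Dict[tuple, np.ndarray] = {}
    for (sample, cluster), idx in meta.groupby(
        ["sample", "cluster"], observed=True
    ).groups.items():
        mask = np.array([b in set(idx) for b in m.barcodes])
        if not mask.any():
            continue
        sums = np.asarray(m.counts[:, mask].sum(axis=1)).ravel().astype(float)
        total = sums.sum()
        cols[(sample, cluster)] = 100.0 * sums / total if total > 0 else sums
    out = pd.DataFrame(cols, index=m.gene_ids)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "cluster"])
    return out


def pseudobulk_percent(m: CountMatrix, meta: pd.DataFrame, gene: str) -> pd.Series:
    """One gene's %UMI per (sample, cluster) stratum."""
    return pseudobulk_percent_table(m, meta).loc[gene]


@dataclass
class MarkerStats:
    gene: str
    group: str
    log_fc: float
    pct_in: float
    pct_out: float
    p_value: float
    padj: float


def _group_stats(
    dense: np.ndarray, in_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene pct_in, pct_out and Seurat-style log fold change."""
    x_in = dense[:, in_mask]
    x_out = dense[:, ~in_mask]
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    log_fc = np.log(
        (np.expm1(x_in).mean(axis=1) + 1) / (np.expm1(x_out).mean(axis=1) + 1)
    )
    return pct_in, pct_out, log_fc


def _markers_for_group(
    dense: np.ndarray,
    gene_ids: Sequence[str],
    in_mask: np.ndarray,
    group: str,
    *,
    only_pos: bool,
    min_pct: float,
    logfc_threshold: float,
    padj_max: float,
    bonferroni_all: bool,
    n_total_genes: int,
) -> List[MarkerStats]:
    pct_in, pct_out, log_fc = _group_stats(dense, in_mask)
    candidate = np.maximum(pct_in, pct_out) >= min_pct
    candidate &= np.abs(log_fc) >= logfc_threshold
    if only_pos:
        candidate &= log_fc > 0
    idx = np.where(candidate)[0]
    if len(idx) == 0:
        return []
    res = mannwhitneyu(
        dense[np.ix_(idx, in_mask)],
        dense[np.ix_(idx, ~in_mask)],
        axis=1,
        alternative="two-sided",
        method="asymptotic",
    )
    n_tests = n_total_genes if bonferroni_all else len(idx)
    out: List[MarkerStats] = []
    for k, gi in enumerate(idx):
        p = float(np.atleast_1d(res.pvalue)[k])
        padj = min(1.0, p * n_tests)
        if padj < padj_max:
            out.append(
                MarkerStats(
                    gene=gene_ids[gi],
                    group=group,
                    log_fc=float(log_fc[gi]),
                    pct_in=float(pct_in[gi]),
                    pct_out=float(pct_out[gi]),
                    p_value=p,
                    padj=padj,
                )
            )
    return out


def find_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    p: MarkerParams = MarkerParams(),
) -> List[MarkerStats]:
    """Per-group marker genes: each group against all remaining cells.

    Groups with fewer than ``min_cells_per_group`` cells are skipped with a
    warning.
    """
    labels = labels.reindex(norm.barcodes)
    if labels.isna().any():
        raise KeyError("cells without a group label")
    dense = np.asarray(norm.values.todense())
    out: List[MarkerStats] = []
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        in_mask = (labels == g).to_numpy()
        if in_mask.sum() < p.min_cells_per_group:
            log.warning("group %s has < %d cells; skipped", g, p.min_cells_per_group)
            continue
        out.extend(
            _markers_for_group(
                dense,
                norm.gene_ids,
                in_mask,
                str(g),
                only_pos=p.only_pos,
                min_pct=p.min_pct,
                logfc_threshold=p.logfc_threshold,
                padj_max=p.padj_max,
                bonferroni_all=p.bonferroni_all_genes,
                n_total_genes=len(norm.gene_ids),
            )
        )
    return out


def de_within_cluster(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    p: MarkerParams = MarkerParams(),
) -> Dict[str, List[MarkerStats]]:
    """Condition contrast inside each cluster (two-sided, not only-positive).

    Runs the marker machinery on the cluster's cells with condition as the
    grouping, reporting from the perspective of the alphabetically first
    condition; clusters missing a condition are skipped.
    """
    meta = meta.loc[norm.barcodes]
    out: Dict[str, List[MarkerStats]] = {}
    for cluster in sorted(meta["cluster"].unique()):
        cmask = (meta["cluster"] == cluster).to_numpy()
        conditions = sorted(meta.loc[cmask, "condition"].unique())
        if len(conditions) < 2:
            log.warning("cluster %s has a single condition; skipped", cluster)
            continue
        dense = np.asarray(norm.values[:, cmask].todense())
        cond = meta.loc[cmask, "condition"].to_numpy()
        ref = conditions[0]
        in_mask = cond == ref
        if in_mask.sum() < p.min_cells_per_group or (~in_mask).sum() < p.min_cells_per_group:
            log.warning("cluster %s: a condition has too few cells; skipped", cluster)
            continue
        out[str(cluster)] = _markers_for_group(
            dense,
            norm.gene_ids,
            in_mask,
            ref,
            only_pos=False,
            min_pct=p.de_min_pct,
            logfc_threshold=p.de_logfc_threshold,
            padj_max=p.de_padj_max,
            bonferroni_all=p.bonferroni_all_genes,
            n_total_genes=len(norm.gene_ids),
        )
    return out


def read_mtx(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """Load a MatrixMarket triplet matrix with gene and barcode TSVs."""
    from scipy.io import mmread

    mat = sp.csr_matrix(mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    return CountMatrix(mat, genes, barcodes)


def write_mtx(m: CountMatrix, mtx_path, genes_path, barcodes_path) -> None:
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), sp.coo_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(m.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)
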