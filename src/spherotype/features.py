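"""Normalization and overdispersion-based variable-gene selection.

Counts are library-size normalized (each cell scaled to a common total)
and log1p-transformed. Overdispersion is scored PAGODA-style: per-gene
winsorized mean and variance, a binned trend of log variance on log mean
fitted across genes, and the score is the trend residual standardized by
the residual spread within local mean bins. Selecting the top-N scores
yields the variable genes used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "OverdispersionScores",
    "normalize",
    "overdispersion_scores",
    "select_top_genes",
    "variance_fraction",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells normalized log-scale expression."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    timepoint: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("value dimensions do not match id lists")


@dataclass
class OverdispersionScores:
    score: np.ndarray  # standardized residual, one per gene
    mean: np.ndarray
    variance: np.ndarray
    rank: np.ndarray  # 1 = most overdispersed; a permutation of 1..n
    gene_ids: list[str]


def normalize(cm: CountMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``scale`` total counts, then log(1 + x)."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = [c for c, t in zip(cm.cell_ids, totals) if t == 0]
        raise ValueError(f"cells with zero total count: {bad[:5]}")
    values = np.log1p(cm.counts / totals[None, :] * scale)
    return ExpressionMatrix(values, list(cm.gene_ids), list(cm.cell_ids),
                            list(cm.timepoint))


def _winsorize_rows(x: np.ndarray, k: int) -> np.ndarray:
    """Clip the k largest values of each row to the (k+1)-th largest."""
    if k <= 0 or x.shape[1] <= k:
        return x.copy()
    part = np.partition(x, x.shape[1] - k - 1, axis=1)
    cap = part[:, x.shape[1] - k - 1]
    return np.minimum(x, cap[:, None])


def overdispersion_scores(
    em: ExpressionMatrix, winsor_k: int = 2, n_bins: int = 30
) -> OverdispersionScores:
    """Score each gene's variance excess over the mean-variance trend.

    The top ``winsor_k`` values of each gene are winsorized so a couple of
    outlier cells cannot dominate the variance. The trend of log variance
    on log mean is a running mean over ``n_bins`` equal-occupancy bins of
    log mean, linearly interpolated; the score is the residual divided by
    the within-bin residual standard deviation, so scores are comparable
    across the expression range.
    """
    x = em.values
    n_genes, n_cells = x.shape
    if n_genes < 30 or n_cells < 10:
        raise ValueError("need at least 30 genes and 10 cells")

    xw = _winsorize_rows(x, winsor_k)
    mean = xw.mean(axis=1)
    var = xw.var(axis=1, ddof=1)
    if np.all(var == 0):
        raise ValueError("all genes constant; mean-variance trend undefined")

    # floor zero variances at the smallest positive variance so the log
    # trend is defined; such genes land at the bottom of the ranking
    min_pos = var[var > 0].min()
    var_f = np.where(var > 0, var, min_pos)
    mean_f = np.where(mean > 0, mean, mean[mean > 0].min()
                      if (mean > 0).any() else 1.0)
    log_mean = np.log(mean_f)
    log_var = np.log(var_f)

    n_bins = int(min(n_bins, max(2, n_genes // 10)))
    order = np.argsort(log_mean, kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // n_genes, n_bins - 1
    )

    centers = np.empty(n_bins)
    trend_pts = np.empty(n_bins)
    for b in range(n_bins):
        sel = bin_of == b
        centers[b] = log_mean[sel].mean()
        trend_pts[b] = log_var[sel].mean()
    trend = np.interp(log_mean, centers, trend_pts)
    resid = log_var - trend

    sd_bin = np.empty(n_bins)
    for b in range(n_bins):
        r = resid[bin_of == b]
        sd_bin[b] = r.std(ddof=1) if r.size > 1 else 0.0
    sd_bin = np.maximum(sd_bin, 1e-8)
    score = resid / sd_bin[bin_of]

    rank = _rank_genes_for_selection(score, mean, em.gene_ids)
    return OverdispersionScores(score, mean, var, rank, list(em.gene_ids))


def _rank_genes_for_selection(
    score: np.ndarray, mean: np.ndarray, gene_ids: list[str]
) -> np.ndarray:
    """Rank 1..n by score desc, ties by mean desc then gene id asc."""
    keys = sorted(
        range(len(gene_ids)),
        key=lambda i: (-score[i], -mean[i], gene_ids[i]),
    )
    rank = np.empty(len(gene_ids), dtype=int)
    for pos, i in enumerate(keys, start=1):
        rank[i] = pos
    return rank


def select_top_genes(scores: OverdispersionScores, n: int = 6000) -> list[str]:
    """The n most overdispersed genes in rank order (all genes if n large)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = np.argsort(scores.rank, kind="stable")
    return [scores.gene_ids[i] for i in order[:n]]


def variance_fraction(em: ExpressionMatrix, genes: list[str]) -> float:
    """Fraction of total per-gene variance carried by ``genes``."""
    if not genes:
        return 0.0
    idx = {g: i for i, g in enumerate(em.gene_ids)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    var = em.values.var(axis=1, ddof=1)
    total = var.sum()
    if total == 0:
        return 0.0
    sel = var[[idx[g] for g in genes]].sum()
    return float(sel / total)
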