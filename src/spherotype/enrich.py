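"""Gene set enrichment analysis: ranking, running-sum ES, permutations.

The engine follows the weighted Kolmogorov-Smirnov formulation: genes are
ranked by a two-class metric (signal-to-noise by default), the running
sum increments by |score|^p / sum_hits |score|^p at members of the set
and decrements by 1/(N - N_hits) elsewhere, and the enrichment score ES
is the signed maximum deviation. The leading edge is the set members at
or before a positive peak (at or after a negative peak). Significance
comes from permutations — phenotype relabeling when both groups are
large enough, otherwise random gene sets of matched size — with the
nominal p, the normalized score NES = ES / mean(same-sign permuted ES),
and a sign-stratified FDR q estimated from the pooled permuted NES
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import ExpressionMatrix
from .io_formats import GeneSet, GeneSetCollection

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "filter_enriched",
]

#: phenotype permutation needs groups at least this large, else gene-set
#: permutation is used (small-sample guidance of the GSEA method)
MIN_GROUP_FOR_PHENOTYPE = 7


@dataclass
class RankedList:
    gene_ids: list[str]  # ordered by score descending
    score: np.ndarray  # aligned with gene_ids
    groups: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if len(self.gene_ids) != self.score.size:
            raise ValueError("one score per gene required")
        if np.any(np.diff(self.score) > 1e-12):
            raise ValueError("scores must be sorted descending")


@dataclass
class EnrichmentResult:
    set_name: str
    ES: float
    NES: float
    p_nominal: float
    fdr_q: float
    leading_edge: frozenset[str]
    size_matched: int  # genes of the set present in the ranked universe


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _s2n(mean_a, sd_a, mean_b, sd_b):
    sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mean_a), 0.2))
    sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mean_b), 0.2))
    return (mean_a - mean_b) / (sd_a + sd_b)


def rank_genes(
    em: ExpressionMatrix,
    cells_a: list[str],
    cells_b: list[str],
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank genes by the signal-to-noise of group A versus group B.

    s2n = (mu_a - mu_b) / (sd_a + sd_b), each sd floored at
    max(0.2 |mu|, 0.2) so low-variance genes cannot produce unbounded
    scores. Ties break lexicographically by gene id.
    """
    if metric != "signal_to_noise":
        raise ValueError(f"unknown metric {metric!r}")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    pos = {c: i for i, c in enumerate(em.cell_ids)}
    ia = [pos[c] for c in cells_a]
    ib = [pos[c] for c in cells_b]
    xa, xb = em.values[:, ia], em.values[:, ib]
    score = _s2n(xa.mean(1), xa.std(1, ddof=1), xb.mean(1), xb.std(1, ddof=1))
    order = sorted(range(len(em.gene_ids)),
                   key=lambda i: (-score[i], em.gene_ids[i]))
    return RankedList([em.gene_ids[i] for i in order], score[order])


# ---------------------------------------------------------------------------
# running-sum enrichment score
# ---------------------------------------------------------------------------

def _running_sum(score: np.ndarray, hit: np.ndarray, p_weight: float):
    """Weighted KS running sum over one ranked list; hit is boolean."""
    n = score.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit some but not all of the universe")
    w = np.abs(score) ** p_weight * hit
    denom = w.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to equal mass
        w = hit.astype(float)
        denom = float(n_hit)
    run = np.cumsum(w / denom - (~hit) / (n - n_hit))
    return run


def enrichment_score(
    rl: RankedList, gs: GeneSet, p_weight: float = 1.0
) -> tuple[float, int, frozenset[str]]:
    """ES, peak index (0-based) and leading edge of one gene set."""
    hit = np.fromiter((g in gs.genes for g in rl.gene_ids), dtype=bool,
                      count=len(rl.gene_ids))
    run = _running_sum(rl.score, hit, p_weight)
    i_max, i_min = int(np.argmax(run)), int(np.argmin(run))
    if run[i_max] >= -run[i_min]:
        es, peak = float(run[i_max]), i_max
        lead = frozenset(g for i, g in enumerate(rl.gene_ids)
                         if hit[i] and i <= peak)
    else:
        es, peak = float(run[i_min]), i_min
        lead = frozenset(g for i, g in enumerate(rl.gene_ids)
                         if hit[i] and i >= peak)
    return es, peak, lead


def _es_batch(
    score_sorted: np.ndarray, member_sorted: np.ndarray, p_weight: float
) -> np.ndarray:
    """ES for many rankings at once; arrays are (N, n_perm)."""
    n = score_sorted.shape[0]
    m = member_sorted.sum(axis=0)
    w = np.abs(score_sorted) ** p_weight * member_sorted
    denom = w.sum(axis=0)
    denom = np.where(denom == 0, 1.0, denom)
    run = np.cumsum(w / denom - (~member_sorted) / (n - m), axis=0)
    idx = np.argmax(np.abs(run), axis=0)
    es = run[idx, np.arange(run.shape[1])]
    return es


# ---------------------------------------------------------------------------
# GSEA with permutation null
# ---------------------------------------------------------------------------

def gsea(
    em: ExpressionMatrix,
    cells_a: list[str],
    cells_b: list[str],
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int = 0,
    p_weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Run GSEA of group A versus group B over a gene-set collection.

    Sets are filtered to [min_size, max_size] members present in the
    universe. ``mode="phenotype"`` permutes group labels and re-ranks;
    ``mode="gene_set"`` keeps the observed ranking and draws random
    same-size gene sets. Groups smaller than 7 cells force gene_set mode.
    Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("phenotype", "gene_set"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "phenotype" and min(len(cells_a), len(cells_b)) < MIN_GROUP_FOR_PHENOTYPE:
        warnings.warn(
            "a group has fewer than 7 cells; falling back to gene_set "
            "permutation"
        )
        mode = "gene_set"

    rng = np.random.default_rng(seed)
    rl = rank_genes(em, cells_a, cells_b)
    universe = rl.gene_ids
    n = len(universe)
    gene_pos = {g: i for i, g in enumerate(universe)}

    kept: list[GeneSet] = []
    members: list[np.ndarray] = []
    for gs in gsc:
        idx = np.array(sorted(gene_pos[g] for g in gs.genes if g in gene_pos),
                       dtype=int)
        if min_size <= idx.size <= max_size:
            kept.append(gs)
            members.append(idx)
    if not kept:
        return []

    observed = [enrichment_score(rl, gs, p_weight) for gs in kept]
    es_obs = np.array([o[0] for o in observed])

    # permuted ES, one row per kept set
    if mode == "gene_set":
        score_sorted = rl.score[:, None]  # ranking fixed
        es_perm = np.empty((len(kept), n_perm))
        null_by_size: dict[int, np.ndarray] = {}
        for i, idx in enumerate(members):
            size = idx.size
            if size not in null_by_size:
                mem = np.zeros((n, n_perm), dtype=bool)
                for j in range(n_perm):
                    mem[rng.choice(n, size=size, replace=False), j] = True
                null_by_size[size] = _es_batch(
                    np.broadcast_to(score_sorted, (n, n_perm)), mem, p_weight
                )
            es_perm[i] = null_by_size[size]
    else:
        es_perm = _phenotype_null(
            em, cells_a, cells_b, members, n_perm, p_weight, rng
        )

    # nominal p: same-sign permutations at least as extreme
    p_nom = np.empty(len(kept))
    nes_obs = np.empty(len(kept))
    nes_perm = np.full_like(es_perm, np.nan)
    for i, es in enumerate(es_obs):
        perm = es_perm[i]
        pos, neg = perm[perm >= 0], perm[perm < 0]
        same = pos if es >= 0 else neg
        p_nom[i] = (np.sum(np.abs(same) >= abs(es)) / same.size
                    if same.size else 1.0)
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg.mean()) if neg.size else np.nan
        scale = mean_pos if es >= 0 else mean_neg
        nes_obs[i] = es / scale if scale and np.isfinite(scale) else 0.0
        if pos.size:
            nes_perm[i, perm >= 0] = perm[perm >= 0] / mean_pos
        if neg.size:
            nes_perm[i, perm < 0] = perm[perm < 0] / mean_neg

    fdr = _fdr_from_nes(nes_obs, nes_perm)

    results = []
    for i, gs in enumerate(kept):
        es, _, lead = observed[i]
        results.append(EnrichmentResult(
            set_name=gs.name,
            ES=es,
            NES=float(nes_obs[i]),
            p_nominal=float(p_nom[i]),
            fdr_q=float(fdr[i]),
            leading_edge=lead,
            size_matched=members[i].size,
        ))
    return results


def _phenotype_null(em, cells_a, cells_b, members, n_perm, p_weight, rng):
    """Permuted ES by relabeling cells and re-ranking, vectorized."""
    pos = {c: i for i, c in enumerate(em.cell_ids)}
    cols = [pos[c] for c in cells_a] + [pos[c] for c in cells_b]
    x = em.values[:, cols]
    m_tot, na = len(cols), len(cells_a)

    mask = np.zeros((m_tot, n_perm))
    for j in range(n_perm):
        mask[rng.choice(m_tot, size=na, replace=False), j] = 1.0
    inv = 1.0 - mask

    x2 = x ** 2
    sa, sb = x @ mask, x @ inv
    qa, qb = x2 @ mask, x2 @ inv
    nb = m_tot - na
    mu_a, mu_b = sa / na, sb / nb
    var_a = np.maximum(qa - na * mu_a ** 2, 0.0) / (na - 1)
    var_b = np.maximum(qb - nb * mu_b ** 2, 0.0) / (nb - 1)
    scores = _s2n(mu_a, np.sqrt(var_a), mu_b, np.sqrt(var_b))

    order = np.argsort(-scores, axis=0, kind="stable")
    score_sorted = np.take_along_axis(scores, order, axis=0)
    es_perm = np.empty((len(members), n_perm))
    membership = np.zeros((scores.shape[0],), dtype=bool)
    for i, idx in enumerate(members):
        membership[:] = False
        membership[idx] = True
        mem_sorted = membership[order]
        es_perm[i] = _es_batch(score_sorted, mem_sorted, p_weight)
    return es_perm


def _fdr_from_nes(nes_obs: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """Sign-stratified FDR q from pooled permuted NES (GSEA procedure)."""
    pool = nes_perm[np.isfinite(nes_perm)]
    pool_pos, pool_neg = pool[pool >= 0], pool[pool < 0]
    obs_pos, obs_neg = nes_obs[nes_obs >= 0], nes_obs[nes_obs < 0]
    q = np.empty_like(nes_obs)
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            num = (np.mean(pool_pos >= nes) if pool_pos.size else 1.0)
            den = (np.mean(obs_pos >= nes) if obs_pos.size else 1.0)
        else:
            num = (np.mean(pool_neg <= nes) if pool_neg.size else 1.0)
            den = (np.mean(obs_neg <= nes) if obs_neg.size else 1.0)
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


def filter_enriched(
    results: list[EnrichmentResult],
    fdr_max: float = 0.05,
    p_max: float = 0.01,
    direction: str = "positive",
) -> list[EnrichmentResult]:
    """Significant results at strict thresholds, matching the ES sign."""
    if direction not in ("positive", "negative", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    out = []
    for r in results:
        if not (r.fdr_q < fdr_max and r.p_nominal < p_max):
            continue
        if direction == "positive" and r.ES <= 0:
            continue
        if direction == "negative" and r.ES >= 0:
            continue
        out.append(r)
    return out
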