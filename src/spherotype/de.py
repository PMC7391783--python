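"""Permutation differential expression, Venn classification, key genes.

Fold changes are pseudocount-shrunken log2 ratios of library-size
normalized group means; significance is an empirical p-value from random
relabeling of group membership. The three pairwise comparisons of a
3-cluster analysis are combined into a Venn classification (which
comparisons each gene is significant in), cluster-specific genes and
markers are derived from consistent-sign significance, and key genes are
the differentially expressed genes most recurrent among the leading
edges of the enrichment-map collections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import EnrichmentResult
from .io_formats import CountMatrix

__all__ = [
    "DERecord",
    "VennClassification",
    "KeyGeneTable",
    "differential_expression",
    "classify_de_venn",
    "marker_genes",
    "key_genes",
]


@dataclass
class DERecord:
    gene: str
    comparison: tuple[str, str]  # (first, second); log2fc is second vs first
    log2fc: float
    p_emp: float
    significant: bool


@dataclass
class VennClassification:
    membership: dict[str, frozenset[tuple[str, str]]]  # gene -> comparisons
    cluster_specific: dict[str, list[str]]
    core: list[str]
    up_in: dict[str, dict[str, bool]] = field(default_factory=dict)
    # up_in[cluster][gene]: direction of a cluster-specific gene


@dataclass
class KeyGeneTable:
    table: pd.DataFrame  # columns: gene, collection, hits at that pairing
    hits: dict[str, int]  # gene -> number of collections hit
    key_genes: list[str]  # argmax-hit genes (all ties)


def _normalized_means(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("cell with zero total count")
    return counts / totals[None, :] * scale


def differential_expression(
    cm: CountMatrix,
    cells_a: list[str],
    cells_b: list[str],
    n_perm: int = 1000,
    pseudocount: float = 1.0,
    seed: int = 0,
    lfc_min: float = 1.5,
    p_max: float = 0.01,
    comparison: tuple[str, str] = ("A", "B"),
) -> list[DERecord]:
    """Per-gene shrunken log2 fold change with label-permutation p-value.

    log2fc = log2((mean_b + c) / (mean_a + c)) on normalized counts;
    p_emp = (1 + #{permuted |log2fc*| >= |log2fc|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    pos = {c: i for i, c in enumerate(cm.cell_ids)}
    cols = [pos[c] for c in cells_a] + [pos[c] for c in cells_b]
    x = _normalized_means(cm.counts[:, cols])
    na, nb = len(cells_a), len(cells_b)
    c = pseudocount

    mean_a = x[:, :na].mean(axis=1)
    mean_b = x[:, na:].mean(axis=1)
    lfc = np.log2((mean_b + c) / (mean_a + c))

    # the null statistic |log2fc*| depends only on the unordered cell
    # partition, and the sampled partitions depend only on the combined
    # cells (sorted) — so swapping the two groups preserves p_emp exactly
    rng = np.random.default_rng(seed)
    order = np.argsort(np.array(cells_a + cells_b, dtype=object))
    xs = x[:, order]
    n_small = min(na, nb)
    mask = np.zeros((na + nb, n_perm))
    for j in range(n_perm):
        mask[rng.choice(na + nb, size=n_small, replace=False), j] = 1.0
    ms = (xs @ mask) / n_small
    ml = (xs @ (1.0 - mask)) / (na + nb - n_small)
    abs_lfc_perm = np.abs(np.log2((ml + c) / (ms + c)))
    exceed = (abs_lfc_perm >= np.abs(lfc)[:, None]).sum(axis=1)
    p_emp = (1.0 + exceed) / (n_perm + 1.0)

    return [
        DERecord(g, comparison, float(lfc[i]), float(p_emp[i]),
                 bool(abs(lfc[i]) > lfc_min and p_emp[i] < p_max))
        for i, g in enumerate(cm.gene_ids)
    ]


def _significance_maps(
    pairwise: dict[tuple[str, str], list[DERecord]],
    lfc_min: float,
    p_max: float,
):
    """Per comparison: {gene: log2fc} restricted to significant genes."""
    sig: dict[tuple[str, str], dict[str, float]] = {}
    for comp, records in pairwise.items():
        sig[comp] = {
            r.gene: r.log2fc for r in records
            if abs(r.log2fc) > lfc_min and r.p_emp < p_max
        }
    return sig


def classify_de_venn(
    pairwise: dict[tuple[str, str], list[DERecord]],
    lfc_min: float = 1.5,
    p_max: float = 0.01,
) -> VennClassification:
    """Venn regions of the three pairwise comparisons.

    A gene is cluster-specific for X when it is significant in both
    comparisons involving X with a consistent direction for X (up in
    both or down in both) and not significant in the remaining
    comparison; genes significant in all three comparisons form the core.
    """
    if len(pairwise) != 3:
        raise ValueError("exactly 3 pairwise comparisons required")
    clusters = sorted({c for comp in pairwise for c in comp})
    if len(clusters) != 3:
        raise ValueError("comparisons must involve exactly 3 clusters")

    sig = _significance_maps(pairwise, lfc_min, p_max)
    comps = list(sig)
    membership: dict[str, frozenset] = {}
    for comp, genes in sig.items():
        for g in genes:
            membership.setdefault(g, frozenset())
    for g in membership:
        membership[g] = frozenset(c for c in comps if g in sig[c])

    core = sorted(g for g, m in membership.items() if len(m) == 3)

    cluster_specific: dict[str, list[str]] = {c: [] for c in clusters}
    up_in: dict[str, dict[str, bool]] = {c: {} for c in clusters}
    for x in clusters:
        involving = [c for c in comps if x in c]
        other = [c for c in comps if x not in c][0]
        for g, m in membership.items():
            if m != frozenset(involving) or g in sig[other]:
                continue
            # direction of the gene in cluster x for each comparison:
            # log2fc is second vs first, so x as second means lfc>0 == up
            dirs = []
            for comp in involving:
                lfc = sig[comp][g]
                dirs.append(lfc > 0 if comp[1] == x else lfc < 0)
            if dirs[0] == dirs[1]:
                cluster_specific[x].append(g)
                up_in[x][g] = dirs[0]
    for x in clusters:
        cluster_specific[x].sort()
    return VennClassification(membership, cluster_specific, core, up_in)


def marker_genes(
    pairwise: dict[tuple[str, str], list[DERecord]],
    lfc_min: float = 2.0,
    p_max: float = 0.01,
) -> dict[str, list[str]]:
    """Cluster-specific genes at the stricter marker thresholds.

    Returns per-cluster gene lists ordered by the gene's largest
    |log2fc| across the cluster's two comparisons, descending.
    """
    venn = classify_de_venn(pairwise, lfc_min=lfc_min, p_max=p_max)
    sig = _significance_maps(pairwise, lfc_min, p_max)
    ordered: dict[str, list[str]] = {}
    for x, genes in venn.cluster_specific.items():
        involving = [c for c in sig if x in c]
        mag = {g: max(abs(sig[c][g]) for c in involving) for g in genes}
        ordered[x] = sorted(genes, key=lambda g: (-mag[g], g))
    return ordered


def key_genes(
    venn: VennClassification,
    enriched_by_collection: dict[str, list[EnrichmentResult]],
    recurrence_min: int = 2,
) -> KeyGeneTable:
    """Link DE genes to recurrent leading-edge genes of map collections.

    Per collection, the representative genes are the leading-edge genes
    appearing in at least ``recurrence_min`` of its pathways (a singleton
    collection's whole leading edge counts). A DE gene scores one hit per
    collection whose representative set contains it; the key genes are
    the genes with the most hits (all ties reported).
    """
    if not enriched_by_collection:
        warnings.warn("no enriched collections; key-gene table is empty")
        return KeyGeneTable(
            pd.DataFrame(columns=["gene", "collection"]), {}, []
        )
    representative: dict[str, set[str]] = {}
    for coll, results in enriched_by_collection.items():
        counts: dict[str, int] = {}
        for r in results:
            for g in r.leading_edge:
                counts[g] = counts.get(g, 0) + 1
        need = 1 if len(results) == 1 else recurrence_min
        representative[coll] = {g for g, n in counts.items() if n >= need}

    de_genes = sorted(venn.membership)
    rows = []
    hits: dict[str, int] = {}
    for g in de_genes:
        n = 0
        for coll, reps in sorted(representative.items()):
            if g in reps:
                rows.append({"gene": g, "collection": coll})
                n += 1
        if n:
            hits[g] = n
    if not hits:
        return KeyGeneTable(
            pd.DataFrame(rows, columns=["gene", "collection"]), {}, []
        )
    best = max(hits.values())
    keys = sorted(g for g, n in hits.items() if n == best)
    return KeyGeneTable(pd.DataFrame(rows), hits, keys)
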