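"""Correlation distance, 2-D embedding, and the two clustering routes.

Cell-cell distance is 1 minus the Pearson correlation of expression
profiles over the selected variable genes (range [0, 2]). Clusters are
found two ways in two spaces: K-means with the number of clusters chosen
by the elbow (second-difference) rule on the SSE curve, and
Gaussian-mixture EM with the component count and covariance structure
chosen by BIC; each applied both to the variable-gene expression space
and to a 2-D UMAP embedding of the correlation distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .features import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "ClusterAssignment",
    "correlation_distance_matrix",
    "embed",
    "elbow_k",
    "kmeans_elbow",
    "em_cluster",
    "cluster_time_composition",
]


@dataclass
class DistanceMatrix:
    d: np.ndarray  # cells x cells, symmetric, zero diagonal, in [0, 2]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.cell_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match cell ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        if self.d.min() < -1e-9 or self.d.max() > 2 + 1e-9:
            raise ValueError("correlation distances must lie in [0, 2]")


@dataclass
class Embedding:
    coords: np.ndarray  # cells x 2
    cell_ids: list[str]
    method: str = "umap"
    seed: int = 0
    n_iter: int = 300


@dataclass
class ClusterAssignment:
    label: np.ndarray  # per-cell int in [0, k)
    k: int
    method: str  # "kmeans" | "em"
    space: str  # "var" | "umap"
    cell_ids: list[str] = field(default_factory=list)
    sse_curve: list[float] | None = None  # SSE at k = 1..kmax (kmeans)

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        present = np.unique(self.label)
        if present.min() < 0 or present.max() >= self.k:
            raise ValueError("labels outside [0, k)")


def correlation_distance_matrix(
    em: ExpressionMatrix, genes: list[str]
) -> DistanceMatrix:
    """d(i, j) = 1 - Pearson r of cells i, j over the given genes."""
    if not genes:
        raise ValueError("gene list is empty")
    idx = {g: i for i, g in enumerate(em.gene_ids)}
    rows = [idx[g] for g in genes]
    x = em.values[rows, :]  # genes x cells
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(em.cell_ids, sd) if s == 0]
        raise ValueError(
            f"correlation undefined for constant cell profiles: {bad[:5]}"
        )
    r = np.corrcoef(x.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(d, list(em.cell_ids))


def embed(dist: DistanceMatrix, n_iter: int = 300, seed: int = 0) -> Embedding:
    """2-D UMAP of the precomputed correlation distances."""
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    n = len(dist.cell_ids)
    if n < 4:
        raise ValueError("embedding needs at least 4 cells")
    import umap  # deferred: numba compilation is slow at import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            metric="precomputed",
            n_epochs=n_iter,
            n_neighbors=min(15, n - 1),
            random_state=seed,
            init="spectral",
        )
        coords = reducer.fit_transform(dist.d)
    return Embedding(np.asarray(coords, dtype=float), list(dist.cell_ids),
                     "umap", seed, n_iter)


# ---------------------------------------------------------------------------
# K-means with the elbow rule
# ---------------------------------------------------------------------------

def elbow_k(sse: list[float] | np.ndarray) -> tuple[int, bool]:
    """Pick k by the second-difference elbow rule on SSE(k), k = 1..kmax.

    Returns (k*, degenerate). k* maximizes SSE(k-1) - 2 SSE(k) + SSE(k+1)
    over interior k; ties break toward smaller k. If the curve is not
    strictly decreasing or no positive second difference stands out, the
    curve has no elbow and k* = 2 is returned with ``degenerate=True``.
    """
    sse = np.asarray(sse, dtype=float)
    kmax = sse.size
    if kmax < 3:
        raise ValueError("elbow rule needs SSE at k = 1..kmax with kmax >= 3")
    if np.any(np.diff(sse) > 1e-12):
        return 2, True
    d2 = sse[:-2] - 2.0 * sse[1:-1] + sse[2:]  # at k = 2..kmax-1
    k_star = int(np.argmax(d2)) + 2
    if d2.max() <= 0:
        return 2, True
    # an elbow needs a clear curvature winner: when the two largest
    # second differences are within 25% the curve is near-flat (e.g. a
    # single blob) and parsimony falls back to k = 2
    if d2.size > 1:
        top, second = np.sort(d2)[-2:][::-1]
        if second > 0 and top < 1.25 * second:
            return 2, True
    return k_star, False


def kmeans_elbow(
    points: np.ndarray, kmax: int = 8, n_init: int = 25, seed: int = 0
) -> ClusterAssignment:
    """K-means over k = 1..kmax; k chosen by the elbow rule on SSE."""
    points = np.asarray(points, dtype=float)
    if kmax < 3:
        raise ValueError("kmax must be >= 3")
    if kmax >= points.shape[0]:
        raise ValueError("kmax must be smaller than the number of cells")
    sse, labels_by_k = [], {}
    for k in range(1, kmax + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels_by_k[k] = km.fit_predict(points)
        sse.append(float(km.inertia_))
    k_star, degenerate = elbow_k(sse)
    if degenerate:
        warnings.warn("SSE curve has no elbow; falling back to k = 2")
    return ClusterAssignment(labels_by_k[k_star], k_star, "kmeans", "var",
                             sse_curve=sse)


def em_cluster(
    points: np.ndarray,
    kmax: int = 8,
    seed: int = 0,
    covariance_types: tuple[str, ...] = ("spherical", "diag", "full"),
    pca_components: int | None = None,
) -> ClusterAssignment:
    """Gaussian-mixture EM; k and covariance structure chosen by BIC.

    With ``pca_components`` set, points are first projected onto that
    many principal components — the standard way to make mixture fitting
    identifiable when dimensions rival the number of cells.
    """
    points = np.asarray(points, dtype=float)
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    if pca_components is not None and points.shape[1] > pca_components:
        from sklearn.decomposition import PCA

        points = PCA(n_components=pca_components,
                     random_state=seed).fit_transform(points)
    best = None
    for k in range(1, kmax + 1):
        for cov in covariance_types:
            gm = GaussianMixture(
                n_components=k, covariance_type=cov, random_state=seed,
                n_init=3, reg_covar=1e-6,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm.fit(points)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if not gm.converged_:
                continue
            bic = gm.bic(points)
            if best is None or bic < best[0]:
                best = (bic, k, gm)
    if best is None:
        raise RuntimeError("no Gaussian-mixture candidate converged")
    _, k, gm = best
    raw = gm.predict(points)
    # relabel to consecutive 0..k'-1 in case a component is empty
    uniq = np.unique(raw)
    remap = {u: i for i, u in enumerate(uniq)}
    labels = np.array([remap[u] for u in raw])
    return ClusterAssignment(labels, len(uniq), "em", "var")


def cluster_time_composition(
    ca: ClusterAssignment, timepoint: list[str]
) -> pd.DataFrame:
    """Per-cluster fraction of cells from each timepoint (rows sum to 1)."""
    if len(timepoint) != ca.label.size:
        raise ValueError("one timepoint label required per cell")
    df = pd.DataFrame({"cluster": ca.label, "timepoint": timepoint})
    tab = pd.crosstab(df["cluster"], df["timepoint"])
    return tab.div(tab.sum(axis=1), axis=0)
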