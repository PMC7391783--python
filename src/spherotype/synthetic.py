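"""Synthetic two-timepoint spheroid scRNA-seq counts with planted structure.

The generator emulates the statistical skeleton of a dissociated
multicellular-tumor-spheroid experiment sampled at an early (D6) and a late
(D19) timepoint: three latent subpopulations whose mixing proportions
depend on the timepoint, negative-binomial counts, per-cluster gene
programs (a block of genes shifted up by a common log2 fold change in that
cluster), log-normal library-size variation, and Bernoulli dropout. Each
program is also emitted as a GMT-compatible gene set, together with
size-matched decoy sets drawn from non-program genes, so the enrichment
stage has planted positives and a calibrated null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import CountMatrix, GeneSet, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SampleSizeSpec",
    "simulate_spheroid_counts",
    "sample_size_proportion",
]

#: default timepoint mixing: rows are clusters, columns are (D6, D19).
#: Chosen so cluster 0 is ~85% late cells and cluster 2 is ~80% early
#: cells at the default per-timepoint cell counts, with cluster 1 mixed —
#: the composition observed for spheroid subpopulations A/B/C.
DEFAULT_MIXING = np.array([
    [0.10, 0.55],
    [0.30, 0.30],
    [0.60, 0.15],
])

TIMEPOINTS = ("D6", "D19")


@dataclass
class SimulationConfig:
    """Parameters of the spheroid-counts generator.

    Defaults give the standard study conditions: 2000 genes, 400 cells
    split 170 early / 230 late (mirroring the 134/230 split of the real
    experiment at a round total), three subpopulations with 100-gene
    programs at log2 fold change 2, NB dispersion 0.3, 20% dropout and
    0.35 log-sd library-size variation.
    """

    n_genes: int = 2000
    n_cells_per_timepoint: tuple[int, int] = (170, 230)
    k_true: int = 3
    mixing: np.ndarray | None = None  # k_true x 2, columns sum to 1
    program_size: int = 100
    program_genes: list[np.ndarray] | None = None
    program_lfc: float = 2.0
    nb_dispersion: float = 0.3
    dropout_rate: float = 0.2
    libsize_sigma: float = 0.35
    n_decoy_sets: int = 5
    seed: int = 0

    def resolved_mixing(self) -> np.ndarray:
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
        elif self.k_true == 3:
            m = DEFAULT_MIXING.copy()
        else:
            m = np.full((self.k_true, 2), 1.0 / self.k_true)
        if m.shape != (self.k_true, 2):
            raise ValueError("mixing must be k_true x 2")
        if not np.allclose(m.sum(axis=0), 1.0):
            raise ValueError("each mixing column must sum to 1")
        return m

    def validate(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        self.resolved_mixing()
        if self.program_genes is not None:
            for idx in self.program_genes:
                if np.any(np.asarray(idx) >= self.n_genes):
                    raise ValueError("program gene index out of range")
        elif self.k_true * self.program_size > self.n_genes:
            raise ValueError("programs exceed gene count")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    cluster_label: np.ndarray  # per-cell int in [0, k_true)
    program_genes: list[np.ndarray]  # per-cluster gene indices
    true_lfc: np.ndarray  # genes x clusters log2 shifts
    planted_gene_sets: GeneSetCollection
    planted_set_names: list[str] = field(default_factory=list)
    decoy_set_names: list[str] = field(default_factory=list)


def simulate_spheroid_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic spheroid dataset.

    Counts for gene g in cell j of cluster c are negative binomial with
    mean ``libsize_j * base_g * 2**lfc[g, c]`` and dispersion
    ``nb_dispersion`` (variance m + dispersion * m^2), then zeroed
    independently with probability ``dropout_rate``. Deterministic given
    ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mixing = cfg.resolved_mixing()
    n6, n19 = cfg.n_cells_per_timepoint
    n_cells = n6 + n19

    labels = np.concatenate([
        rng.choice(cfg.k_true, size=n6, p=mixing[:, 0]),
        rng.choice(cfg.k_true, size=n19, p=mixing[:, 1]),
    ])
    timepoint = ["D6"] * n6 + ["D19"] * n19

    if cfg.program_genes is not None:
        programs = [np.asarray(p, dtype=int) for p in cfg.program_genes]
    else:
        # disjoint blocks drawn from a shuffled gene order
        order = rng.permutation(cfg.n_genes)
        programs = [
            order[c * cfg.program_size: (c + 1) * cfg.program_size]
            for c in range(cfg.k_true)
        ]

    true_lfc = np.zeros((cfg.n_genes, cfg.k_true))
    for c, idx in enumerate(programs):
        true_lfc[idx, c] = cfg.program_lfc

    # baseline means: log-normal across genes, typical scRNA-seq skew
    base = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    libsize = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=n_cells)

    mean = base[:, None] * np.power(2.0, true_lfc[:, labels]) * libsize[None, :]
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    if cfg.dropout_rate > 0:
        counts = np.where(
            rng.random(counts.shape) < cfg.dropout_rate, 0, counts
        )

    gene_ids = [f"G{g:05d}" for g in range(cfg.n_genes)]
    cell_ids = [f"C{j:04d}-{tp}" for j, tp in enumerate(timepoint)]
    cm = CountMatrix(counts, gene_ids, cell_ids, timepoint)

    sets: list[GeneSet] = []
    planted_names, decoy_names = [], []
    for c, idx in enumerate(programs):
        if idx.size == 0:  # null model: no program to plant
            continue
        name = f"PROGRAM_CLUSTER_{c}"
        sets.append(GeneSet(name, f"planted program of cluster {c}",
                            frozenset(gene_ids[g] for g in idx)))
        planted_names.append(name)
    nonprog = np.setdiff1d(np.arange(cfg.n_genes), np.concatenate(programs)
                           if programs else np.array([], dtype=int))
    size = max((p.size for p in programs), default=cfg.program_size)
    for d in range(cfg.n_decoy_sets if size > 0 else 0):
        idx = rng.choice(nonprog, size=min(size, nonprog.size), replace=False)
        name = f"DECOY_SET_{d}"
        sets.append(GeneSet(name, "size-matched decoy",
                            frozenset(gene_ids[g] for g in idx)))
        decoy_names.append(name)

    truth = SyntheticTruth(
        cluster_label=labels,
        program_genes=programs,
        true_lfc=true_lfc,
        planted_gene_sets=GeneSetCollection("planted", sets),
        planted_set_names=planted_names,
        decoy_set_names=decoy_names,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# sample size for a proportion
# ---------------------------------------------------------------------------

@dataclass
class SampleSizeSpec:
    """Normal-approximation sample size for estimating a proportion.

    p is the anticipated proportion, margin the half-width E of the
    confidence interval and confidence the coverage level; z is the
    corresponding two-sided standard-normal quantile.
    """

    p: float
    margin: float = 0.05
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be strictly inside (0, 1)")
        if not 0.0 < self.margin < 1.0:
            raise ValueError("margin must be in (0, 1)")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(1.0 - (1.0 - self.confidence) / 2.0))


def sample_size_proportion(spec: SampleSizeSpec) -> int:
    """n = ceil(z^2 p (1-p) / E^2), no finite-population correction."""
    n = spec.z ** 2 * spec.p * (1.0 - spec.p) / spec.margin ** 2
    return int(np.ceil(n))
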