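import numpy as np
import pytest

import spherotype as st


@pytest.fixture
def tiny_counts() -> st.CountMatrix:
    """3 genes x 4 cells with distinctive values for parsing tests."""
    counts = np.array([
        [5, 0, 2, 1],
        [1, 3, 0, 0],
        [0, 2, 4, 7],
    ])
    return st.CountMatrix(counts, ["gA", "gB", "gC"],
                          ["c1", "c2", "c3", "c4"],
                          ["D6", "D6", "D19", "D19"])


@pytest.fixture(scope="session")
def null_dataset():
    """One-population dataset with no planted signal (exchangeable null)."""
    cfg = st.SimulationConfig(
        n_genes=1000, n_cells_per_timepoint=(30, 30), k_true=1,
        mixing=np.array([[1.0, 1.0]]), program_genes=[np.array([], int)],
        program_lfc=0.0, seed=5,
    )
    cm, _ = st.simulate_spheroid_counts(cfg)
    return st.filter_qc(cm, min_genes_per_cell=50)


@pytest.fixture(scope="session")
def small_planted():
    """Reduced planted dataset for fast recovery checks (lfc = 3)."""
    cfg = st.SimulationConfig(
        n_genes=800, n_cells_per_timepoint=(60, 90), program_size=40,
        program_lfc=3.0, seed=21,
    )
    cm, truth = st.simulate_spheroid_counts(cfg)
    filtered = st.filter_qc(cm, min_genes_per_cell=100)
    kept = [i for i, c in enumerate(cm.cell_ids)
            if c in set(filtered.cell_ids)]
    truth.cluster_label = truth.cluster_label[kept]
    return filtered, truth
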