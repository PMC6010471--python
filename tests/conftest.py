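import numpy as np
import pytest

import spotfactor as sf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_count_matrix(rng, n_spots=6, n_genes=9, high=20, section="s"):
    counts = rng.integers(0, high, size=(n_spots, n_genes))
    genes = [f"g{i:03d}" for i in range(n_genes)]
    spots = [sf.SpotId(section, i % 4, i // 4) for i in range(n_spots)]
    return sf.CountMatrix(genes, spots, counts)


@pytest.fixture
def small_cm(rng):
    return random_count_matrix(rng)


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale ground truth shared across tests (10x10 grid, T=3)."""
    spec = sf.SimulationSpec(
        grid_rows=10, grid_cols=10, n_genes=80, markers_per_factor=8, seed=7
    )
    return sf.make_truth(spec)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return sf.simulate_dataset(small_truth)
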