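import numpy as np
import pytest

from scrden import GeneExpressionMatrix, simulate_branching


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """Random 10 genes x 8 cells matrix with distinct values."""
    values = rng.gamma(2.0, 2.0, size=(10, 8))
    return GeneExpressionMatrix(
        values, [f"g{i}" for i in range(10)], [f"c{j}" for j in range(8)])


@pytest.fixture(scope="session")
def linear_data():
    """1-branch synthetic dataset shared by the slower tests."""
    return simulate_branching(n_genes=400, n_cells=300, n_branches=1, seed=1)


@pytest.fixture(scope="session")
def bifurcating_data():
    return simulate_branching(n_genes=400, n_cells=300, n_branches=2, seed=1)
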