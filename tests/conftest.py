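import numpy as np
import pytest

from dissonet.dag import WeightedDag
from dissonet.synthetic import ggm_correlation, sample_random_ggm


@pytest.fixture
def chain_dag() -> WeightedDag:
    """A -> B -> C with coefficients 0.5, 0.5."""
    edges = {("A", "B"): 0.5, ("B", "C"): 0.5}
    return WeightedDag(["A", "B", "C"], list(edges), dict(edges))


@pytest.fixture
def ggm_data():
    """(true partial-correlation matrix, data) from a sparse 8-node GGM."""
    R = sample_random_ggm(8, 10, seed=42)
    rng = np.random.default_rng(7)
    X = rng.multivariate_normal(np.zeros(8), ggm_correlation(R), size=2000)
    X = (X - X.mean(0)) / X.std(0)
    return R, X


def make_dependent_data(n: int, p: int, seed: int) -> np.ndarray:
    """Standardized data with a few strong structural dependencies."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if p >= 2:
        X[:, 1] += 0.7 * X[:, 0]
    if p >= 4:
        X[:, 3] += 0.5 * X[:, 2]
    if p >= 5:
        X[:, 4] += 0.4 * X[:, 1]
    return (X - X.mean(0)) / X.std(0)
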