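import numpy as np
import pytest

from clinms.synthetic import Dataset, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_binary_problem(rng):
    """A small well-conditioned logistic problem (n=60, q=3)."""
    Z = rng.standard_normal((60, 3))
    gamma = np.array([0.5, -1.0, 0.8])
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-(0.3 + Z @ gamma))))
    if y.sum() in (0, 60):  # pragma: no cover - rng guard
        y[0] = 1 - y[0]
    return Z, y.astype(float)


@pytest.fixture
def case2_dataset():
    """One simulated dataset in the feature-dominated regime (mu=2)."""
    return simulate_dataset(SimulationConfig(n=200, p=100, mu=2.0, seed=5))
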