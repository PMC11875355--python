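import numpy as np
import pytest

from nfrfs import SolverConfig, make_synthetic, minmax_normalize


@pytest.fixture(scope="session")
def bench():
    """The standard synthetic benchmark: 3 clusters, 10 informative + 190 noise."""
    return minmax_normalize(make_synthetic(seed=0))


@pytest.fixture
def small_config():
    """A quick solver configuration for unit tests."""
    return SolverConfig(alpha=1.0, beta=1.0, p=0.5, k=3, lam=1e4, l=3, max_iter=30, tol=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
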