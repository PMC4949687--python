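import numpy as np
import pytest

from cortimap import make_icosphere


@pytest.fixture(scope="session")
def small_mesh():
    """162-vertex icosphere, 10 mm radius."""
    return make_icosphere(2, 10.0)


@pytest.fixture(scope="session")
def medium_mesh():
    """642-vertex icosphere, 50 mm radius (hemisphere-like area scale)."""
    return make_icosphere(3, 50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def binomial_bounds(n: int, p: float, conf: float = 0.95):
    """Two-sided binomial count bounds at the given confidence."""
    from scipy import stats

    lo = stats.binom.ppf((1 - conf) / 2, n, p)
    hi = stats.binom.ppf(1 - (1 - conf) / 2, n, p)
    return int(lo), int(hi)
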