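import numpy as np
import pytest

from pssizer import LongitudinalDataset, SplineSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240531)


@pytest.fixture
def small_spec():
    """Small basis (M = 12) for fast exact-oracle comparisons."""
    return SplineSpec(n_internal_knots=8, domain_lo=0.0, domain_hi=1.0)


def make_longitudinal(
    rng,
    truth=lambda t: np.sin(2 * np.pi * t) * 2.0 + 3.0,
    N=5,
    n_i=10,
    sigma_eps=0.7,
    sigma_b=1.5,
    t_lo=0.0,
    t_hi=1.0,
):
    """Balanced longitudinal sample around a known smooth truth."""
    t = np.tile(np.linspace(t_lo, t_hi, n_i), N)
    g = np.repeat(np.arange(N), n_i)
    b = rng.normal(0.0, sigma_b, N)
    y = truth(t) + b[g] + rng.normal(0.0, sigma_eps, len(t))
    return LongitudinalDataset(subject=g, time=t, value=y)


@pytest.fixture
def small_data(rng):
    return make_longitudinal(rng)
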