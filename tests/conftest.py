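import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import locpois as lp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_poisson_data(seed=0, n=100, p=2, beta=(1.0, 0.5, -0.3), lo=0.0, hi=2.0):
    """Log-linear Poisson data on uniform predictors; independent of the generator module."""
    r = np.random.default_rng(seed)
    X = r.uniform(lo, hi, size=(n, p))
    beta = np.asarray(beta, dtype=float)
    mu = np.exp(beta[0] + X @ beta[1:])
    y = r.poisson(mu)
    return lp.CountDataset(y=y, X=X)


@pytest.fixture
def small_data():
    return make_poisson_data(seed=7, n=40)


@pytest.fixture
def stunting():
    return lp.stunting_fixture()
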