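import logging

import numpy as np
import pytest

from bayeseg import CoefficientPrior, TimeSeries, make_linear_basis


@pytest.fixture(autouse=True)
def _quiet_prior_width_warnings(caplog):
    # the prior-width condition is advisory; keep test output readable
    logging.getLogger("bayeseg.marginal").setLevel(logging.ERROR)
    logging.getLogger("bayeseg.engine").setLevel(logging.ERROR)
    logging.getLogger("bayeseg.segstats").setLevel(logging.ERROR)
    yield


@pytest.fixture
def toy_ts():
    """Three flat points (0,1), (1,1), (2,1), one replicate."""
    return TimeSeries(x=[0.0, 1.0, 2.0], y=[[1.0, 1.0, 1.0]])


@pytest.fixture
def toy_prior():
    """Prior box m1 in [0, 2], m2 in [-1, 1] (volume 4)."""
    return CoefficientPrior([0.0, -1.0], [2.0, 1.0])


@pytest.fixture
def linear_basis():
    return make_linear_basis()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_timeseries(rng, N, N_r=1, sigma=None, x_scale=1.0):
    x = np.sort(rng.uniform(0.0, x_scale * N, N))
    while np.any(np.diff(x) <= 0):
        x = np.sort(rng.uniform(0.0, x_scale * N, N))
    y = rng.normal(0.0, 1.0, (N_r, N)) + rng.uniform(-2, 2) + rng.uniform(-1, 1) * x
    return TimeSeries(x=x, y=y, sigma=sigma)
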