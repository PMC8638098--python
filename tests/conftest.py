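import numpy as np
import pytest

import wdtrace as w


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """p=10 scenario with 4 planted differential edges."""
    return w.make_precision_pair(10, 5, 4, magnitude=0.3, seed=2)


@pytest.fixture
def small_cov(small_scenario):
    scn = small_scenario
    X = w.sample_expression(scn.theta_X, 200, seed=11)
    Y = w.sample_expression(scn.theta_Y, 200, seed=22)
    return w.CovariancePair.from_samples(X, Y)
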