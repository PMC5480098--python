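import numpy as np
import pytest

from postsel.estimators import TuningGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_grid():
    """Coarse tuning grid for fast unit tests."""
    return TuningGrid(n_lambda=15, lambda_min_ratio=1e-2,
                      enet_lambda2=(0.0, 0.1, 1.0), enet_n_fractions=11,
                      phis=(0.0, 0.5, 1.0), ridge_lambdas=(1e-3, 1e-2, 1e-1),
                      lambda2_grid=(0.01, 0.1), fold_seed=7)


@pytest.fixture
def linear_toy(rng):
    """Small sparse linear problem with a known strong support."""
    n, p = 120, 8
    X = rng.standard_normal((n, p))
    beta = np.array([2.0, -1.5, 0, 0, 0, 0, 0, 0])
    y = 0.5 + X @ beta + rng.standard_normal(n)
    return X, y, beta


@pytest.fixture
def logistic_toy(rng):
    n, p = 200, 6
    X = rng.standard_normal((n, p))
    beta = np.array([1.5, -1.0, 0, 0, 0, 0])
    eta = -0.3 + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y, beta
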