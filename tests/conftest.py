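import numpy as np
import pytest

from gammaboot import FitConfig, ModelParams, RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_point_data():
    """Tiny hand-checkable fixture: n=5, p=2."""
    X = np.array(
        [
            [0.5, -1.2],
            [-0.3, 0.8],
            [1.1, 0.4],
            [-0.7, -0.5],
            [0.2, 1.5],
        ]
    )
    y = np.array([1.0, -0.4, 2.3, -1.1, 0.6])
    return RegressionData(y=y, X=X)


@pytest.fixture
def clean_data():
    """Clean generative data with known truth: n=50, p=2."""
    g = np.random.default_rng(7)
    X = g.standard_normal((50, 2))
    beta = np.array([2.0, -1.0])
    y = 0.5 + X @ beta + g.standard_normal(50)
    return RegressionData(y=y, X=X), ModelParams(0.5, beta, 1.0)


@pytest.fixture
def default_config():
    return FitConfig()
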