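import numpy as np
import pytest
from numpy.random import default_rng

from beeloop import ModelParams


@pytest.fixture
def params() -> ModelParams:
    """Calibrated population-level parameters."""
    return ModelParams()


@pytest.fixture
def rng():
    return default_rng(12345)


@pytest.fixture(scope="session")
def nest():
    return np.zeros(2)
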