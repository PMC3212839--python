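import numpy as np
import pytest

from glikfreq import ErrorMatrix


@pytest.fixture
def err_uniform_01():
    """Uniform matrix with each off-diagonal entry 0.01 (total 3%)."""
    return ErrorMatrix.uniform(0.03)


@pytest.fixture
def err_default():
    return ErrorMatrix.uniform()


@pytest.fixture
def err_zero():
    return ErrorMatrix.uniform(0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
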