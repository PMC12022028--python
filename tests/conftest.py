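import numpy as np
import pytest

from hiercausal import ModelParams, default_t2


@pytest.fixture(scope="session")
def t2():
    """Shared direction-concentration calibration table."""
    return default_t2()


@pytest.fixture()
def params():
    return ModelParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
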