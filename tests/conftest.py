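import numpy as np
import pytest

from ldopapop import defaults as D


@pytest.fixture(scope="session")
def parent_theta():
    return dict(D.PARENT_THETA)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
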