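import warnings

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # zero-count drops and perfect-separation notices are exercised on purpose
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        warnings.filterwarnings("ignore", message=".*zero count.*")
        warnings.filterwarnings("ignore", message=".*Perfect separation.*")
        yield
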