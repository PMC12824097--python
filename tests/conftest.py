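import numpy as np
import pytest

from memfluct.synthetic import preset_params


@pytest.fixture(scope="session")
def tirf_preset():
    """Default mechanical parameters + acquisition settings (2,048 @ 20 Hz)."""
    params, acq = preset_params("tirf-irm")
    return params, acq


@pytest.fixture(scope="session")
def tirf_params(tirf_preset):
    return tirf_preset[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
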