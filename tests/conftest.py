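import numpy as np
import pytest

from ribodrop.presets import CMDEX_PLYS, NoiseSpec


@pytest.fixture
def preset():
    return CMDEX_PLYS


@pytest.fixture
def no_noise():
    return NoiseSpec(0.0, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
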