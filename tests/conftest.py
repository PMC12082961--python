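import numpy as np
import pytest

from veinmod import synthetic
from veinmod.types import Condition


@pytest.fixture
def pb10_pattern():
    return synthetic.make_breath_pattern(Condition.PB10, 50.0)


@pytest.fixture
def pb3_pattern():
    return synthetic.make_breath_pattern(Condition.PB3, 50.0)


@pytest.fixture
def sb_pattern():
    return synthetic.make_breath_pattern(Condition.SB, 50.0, seed=7)


@pytest.fixture
def noise_free_scene():
    return synthetic.SceneParams(speckle_sd=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
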