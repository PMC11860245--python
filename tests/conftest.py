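import numpy as np
import pytest

from stst.fixtures import translating_texture
from stst.twostream import MSOE, make_fixture_model


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def spatial_fixture_model():
    return make_fixture_model(0, arity=1)


@pytest.fixture(scope="session")
def msoe_model():
    return MSOE(n_scales=2)


@pytest.fixture(scope="session")
def tiny_texture():
    """12x12, 4-frame rightward translating texture."""
    return translating_texture(12, 12, 4, speed=1.0, direction=0.0, seed=3)
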