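import numpy as np
import pytest

from torchsearch import build_layout
from torchsearch.environment import SKEWED, UNIFORM, ConditionSpec


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def skewed_spec():
    return ConditionSpec(SKEWED, skewed_target=0)


@pytest.fixture
def uniform_spec():
    return ConditionSpec(UNIFORM)
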