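import numpy as np
import pytest

from gazebeta.kinematics import Condition, ScreenGeometry, default_params
from gazebeta.montage import default_adjacency


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def params_by_condition():
    return {c: default_params(c) for c in Condition}


@pytest.fixture(scope="session")
def close_params(params_by_condition):
    return params_by_condition[Condition.CLOSE]


@pytest.fixture(scope="session")
def graph():
    return default_adjacency()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
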