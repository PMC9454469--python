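import numpy as np
import pytest

from celldose.decay import make_monoenergetic
from celldose.scoeff import CellModel
from celldose.transport import default_models


@pytest.fixture(scope="session")
def cell():
    """The reference cell geometry: 6-um cell, 5-um nucleus."""
    return CellModel(6.0, 5.0)


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def electron_50kev():
    return make_monoenergetic("electron", 0.05)


@pytest.fixture(scope="session")
def alpha_5mev():
    return make_monoenergetic("alpha", 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
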