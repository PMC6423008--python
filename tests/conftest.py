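import numpy as np
import pytest

from bindkin.itc import default_protocol
from bindkin.reference import BINDING_PARAMS, KINETIC_SCHEMES


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def gcda_ph58():
    return BINDING_PARAMS[("GCDA", 5.8)]


@pytest.fixture(scope="session")
def gca_ph58():
    return BINDING_PARAMS[("GCA", 5.8)]


@pytest.fixture(scope="session")
def scheme_gcda_ph58():
    return KINETIC_SCHEMES[("GCDA", 5.8)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
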