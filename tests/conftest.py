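import warnings

import numpy as np
import pytest

from betacell import make_fixture_network
from betacell.simulate import initial_state, steady_state


@pytest.fixture(scope="session")
def reduced():
    return make_fixture_network("reduced")


@pytest.fixture(scope="session")
def full():
    return make_fixture_network("full")


@pytest.fixture(scope="session")
def reduced_low_ss(reduced):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return steady_state(reduced, reduced.parameters, initial_state(reduced),
                            {"GLC_e": 2.8}, horizon=3000.0)


@pytest.fixture(scope="session")
def reduced_high_ss(reduced, reduced_low_ss):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return steady_state(reduced, reduced.parameters, reduced_low_ss.state,
                            {"GLC_e": 16.7}, horizon=3000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)
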