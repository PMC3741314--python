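import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rootniche.grid import DEFAULT_GRID
from rootniche.plants import PlantParams
from rootniche.rooting import standard_profiles
from rootniche.soil import COARSE, FINE


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def coarse():
    return COARSE


@pytest.fixture(scope="session")
def fine():
    return FINE


@pytest.fixture(scope="session")
def profiles():
    return standard_profiles()


@pytest.fixture(scope="session")
def plant_params():
    return PlantParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20130812)
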