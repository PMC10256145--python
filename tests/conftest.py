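import numpy as np
import pytest

from contrastnorm import ScreenGeometry, default_archetypes
from contrastnorm.synthetic import SimConfig


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture()
def sim_config() -> SimConfig:
    return SimConfig(seed=11, n_cells=4, n_flies=2)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
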