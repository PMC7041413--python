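import numpy as np
import pytest

from bumplearn.population import PopulationGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid100():
    return PopulationGrid(1, 100)


@pytest.fixture
def grid2d():
    return PopulationGrid(2, 10)
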