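import numpy as np
import pytest

from benthoscape import pipeline as pl
from benthoscape.config import BenthoscapeConfig


@pytest.fixture(scope="session")
def small_config() -> BenthoscapeConfig:
    """A reduced survey for fast structural tests."""
    return BenthoscapeConfig(grid_shape=(24, 30), n_stations=60, seed=11)


@pytest.fixture(scope="session")
def small_survey(small_config):
    return pl.simulate_survey(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
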