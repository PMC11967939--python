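import numpy as np
import pytest

from benthoscape.geostat import VariogramModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spherical_model():
    return VariogramModel("spherical", 0.1, 1.0, 2000.0)


@pytest.fixture
def small_survey():
    """A small synthetic survey bundle shared across integration tests."""
    from benthoscape.synthetic import SimulationConfig, simulate_survey
    cfg = SimulationConfig(extent=(0.0, 6000.0, 0.0, 6000.0),
                           cell_size_m=300.0, n_stations=40, seed=11)
    return simulate_survey(cfg)
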