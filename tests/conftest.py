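import numpy as np
import pytest

from reefheat.dhw import annual_max_dhw, dhw, hotspot
from reefheat.synthetic import ScenarioConfig, simulate_sst


@pytest.fixture(scope="session")
def small_scenario():
    """A compact 12-year default-regime scenario shared across tests."""
    cfg = ScenarioConfig(
        n_years=12,
        nlat=4,
        nlon=6,
        blocks=(),
        seed=11,
    )
    cube, mmm, oni, reefs = simulate_sst(cfg)
    return cfg, cube, mmm, oni, reefs


@pytest.fixture(scope="session")
def small_annual_max(small_scenario):
    _, cube, mmm, _, _ = small_scenario
    d = dhw(hotspot(cube, mmm))
    return annual_max_dhw(d)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
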