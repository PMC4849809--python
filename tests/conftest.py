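import numpy as np
import pytest

from respcrit import (
    FishProfile,
    RespirometerConfig,
    SimulationConfig,
    WaterConditions,
)


@pytest.fixture
def freshwater_15c():
    return WaterConditions(temperature=15.0, salinity=0.0)


@pytest.fixture
def seawater_15c():
    return WaterConditions(temperature=15.0, salinity=35.0)


@pytest.fixture
def regulator():
    return FishProfile(kind="regulator", rmr=100.0, body_mass=0.05, pcrit=5.15)


@pytest.fixture
def conformer():
    return FishProfile(kind="conformer", rmr=1.0, body_mass=0.05, conform_slope=10.0)


@pytest.fixture
def closed_chamber(freshwater_15c):
    return RespirometerConfig(
        volume_respirometer=2.0,
        volume_fish=0.1,
        body_mass=0.05,
        mode="closed",
        conditions=freshwater_15c,
    )


@pytest.fixture
def descending_grid():
    return np.linspace(20.0, 1.0, 30)
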