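import logging

import numpy as np
import pytest

from bruisemap.pressure_io import SensorSpec
from bruisemap.synthetic_data import SimulatorParams, simulate_impact

# velocity-series truncation warnings are expected all over the suite
logging.getLogger("bruisemap.energy_reconstruction").setLevel(logging.ERROR)

HEIGHTS = (0.05, 0.125, 0.2)


@pytest.fixture(scope="session")
def sims_by_height():
    """One default-parameter simulation per study height, shared."""
    return {h: simulate_impact(SimulatorParams(drop_height_m=h)) for h in HEIGHTS}


@pytest.fixture(scope="session")
def sim_h125(sims_by_height):
    return sims_by_height[0.125]


@pytest.fixture()
def small_sensor():
    return SensorSpec(rows=8, cols=8, pitch_mm=1.9, frame_rate=60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def coarse_params(h: float, **kw) -> SimulatorParams:
    """Cheap simulator parameters for tests that don't need fine accuracy."""
    kw.setdefault("fine_dt", 1e-4)
    return SimulatorParams(drop_height_m=h, **kw)
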