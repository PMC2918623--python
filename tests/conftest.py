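import numpy as np
import pytest

from aiis import (ControllerParams, EngineParams, PatientParams, SensorParams,
                  build_scenario)
from aiis.engine import replicate_seeds, run_closed_loop


@pytest.fixture
def patient():
    return PatientParams()


@pytest.fixture
def controller():
    return ControllerParams()


@pytest.fixture
def quiet_sensor():
    """Sensor with the noise generator switched off."""
    return SensorParams(noise_variance=0.0)


@pytest.fixture(scope="session")
def challenge_replicates():
    """Eleven seeded closed-loop replicates of each positive challenge.

    Shared across the acceptance tests that look at different metrics of the
    same runs (basal rate, plasma insulin, peaks, settling times).
    """
    out = {}
    for kind in ("mild", "moderate", "severe"):
        scn = build_scenario(kind)
        out[kind] = [run_closed_loop(scenario=scn, seed=s)
                     for s in replicate_seeds(0, 11)]
    return out


def median(values):
    return float(np.median(np.asarray(values, dtype=float)))
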