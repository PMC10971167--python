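import numpy as np
import pytest

from stripekin.kinetics import TraceModel
from stripekin.simulate import SimulationConfig, simulate_trace, default_timebase


@pytest.fixture(scope="session")
def timebase():
    """Default two-rate timebase: 10 s baseline, 1 fps then 0.2 fps, ~10 min window."""
    return default_timebase()


@pytest.fixture(scope="session")
def small_sim_config():
    """A desk-scale single-nucleus scene (96x96, one focal plane)."""
    return SimulationConfig(image_shape=(96, 96), n_z=1, n_nuclei=1, seed=0)


def make_model(lag=13.0, k_on=0.05, k_off=0.01, plateau=120.0, delta=1.0, tA=10.0):
    tB = tA + lag
    assoc = np.log(20.0) / k_on
    return TraceModel(delta_max=delta, k_on=k_on, k_off=k_off, tB=tB, tD=tB + assoc + plateau)


@pytest.fixture
def noiseless_trace(timebase):
    model = make_model()
    return simulate_trace(model, timebase, 0.0, seed=0), model
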