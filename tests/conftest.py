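import numpy as np
import pytest

from enosekit.signals import BreathSample, SensorTrace
from enosekit.synthetic import CohortSpec, SensorModel, default_sensor_bank


@pytest.fixture(scope="session")
def sensor_bank():
    return default_sensor_bank()


@pytest.fixture(scope="session")
def small_spec():
    """A small default-conditions cohort spec (10 per class)."""
    return CohortSpec(n_healthy=10, n_sick=10, seed=7)


@pytest.fixture
def tent_trace():
    """The worked hand-oracle trace [0, 1, 2, 1, 0] at dt = 1 s."""
    return SensorTrace("S01", 1.0, np.array([0.0, 1.0, 2.0, 1.0, 0.0]))


@pytest.fixture
def noiseless_model():
    return SensorModel("S01", base_amplitude=1.0, rise_tau=8.0, decay_tau=20.0,
                       noise_sd=0.0)


def make_noise_sample(rng, n_sensors=28, n=121, sd=0.1, sample_id="noise"):
    traces = [
        SensorTrace(f"S{j + 1:02d}", 1.0, rng.normal(0.0, sd, n) + 1.0)
        for j in range(n_sensors)
    ]
    return BreathSample(sample_id, 0, traces)
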