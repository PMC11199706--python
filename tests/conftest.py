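import numpy as np
import pytest

from fluokit import BleachSpec, EventSchedule, SensorSimParams, simulate_photometry_session


@pytest.fixture
def params():
    """Clean sensor parameters: no bleach, no artifacts, no noise."""
    return SensorSimParams()


@pytest.fixture
def noisy_params():
    return SensorSimParams(
        motion_sd=0.02,
        noise_sd=0.005,
        bleach=BleachSpec("biexponential"),
        seed=11,
    )


@pytest.fixture
def injection_schedule():
    """2-min baseline then an injection marker, 10-min session."""
    return EventSchedule([(120.0, "injection", 0.0)], 600.0, "injection")


@pytest.fixture
def short_session(noisy_params, injection_schedule):
    """A small injection session at a reduced rate for fast pipeline tests."""
    return simulate_photometry_session(noisy_params, injection_schedule, rate=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
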