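import numpy as np
import pytest

from nirsdyn.protocol import ProtocolSchedule
from nirsdyn.simulate import OscillatorSpec, generate_recording


@pytest.fixture(scope="session")
def schedule() -> ProtocolSchedule:
    return ProtocolSchedule()


@pytest.fixture(scope="session")
def constant_lf() -> OscillatorSpec:
    """LF oscillator without phase modulation (for recovery oracles)."""
    return OscillatorSpec(center_frequency=0.05, pole_modulus=0.92, amplitude_scale=1.0)


@pytest.fixture(scope="session")
def constant_hf() -> OscillatorSpec:
    return OscillatorSpec(center_frequency=0.20, pole_modulus=0.90, amplitude_scale=0.8)


@pytest.fixture(scope="session")
def small_recording(schedule, constant_lf, constant_hf):
    """Two-channel artifact-free recording with unmodulated oscillators."""
    return generate_recording(
        schedule=schedule,
        n_channels=2,
        lf=constant_lf,
        hf=constant_hf,
        noise_sd=0.05,
        seed=123,
        artifacts=False,
    )
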