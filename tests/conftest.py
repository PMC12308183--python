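import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def open_solenoid():
    """Noiseless 10-unit solenoid with non-trivial yaw/pitch/roll."""
    from repeatgeom.synthetic import SolenoidParams, generate_solenoid
    return generate_solenoid(SolenoidParams(
        n_units=10, yaw0=0.3, pitch0=0.1, roll0=0.25, radius=20.0, seed=1))


@pytest.fixture
def closed_ring8():
    """Noiseless closed 8-unit ring (TIM-barrel-like topology)."""
    from repeatgeom.synthetic import SolenoidParams, generate_solenoid
    return generate_solenoid(SolenoidParams(n_units=8, closed=True, seed=1))
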