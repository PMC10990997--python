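import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iapflow import ArterialCurve, KineticParams, simulate_arterial_curve

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture
def constant_curve():
    """Constant arterial input of 100 nCi/ml over the full minute."""
    return ArterialCurve(np.array([0.0, 60.0]), np.array([100.0, 100.0]))


@pytest.fixture
def ramp_curve():
    """Linear ramp C_A(t) = 2t nCi/ml sampled every 3 s."""
    t = np.linspace(0.0, 60.0, 21)
    return ArterialCurve(t, 2.0 * t)


@pytest.fixture
def gamma_curve():
    """Seeded noisy gamma-variate input, the generator's default shape."""
    return simulate_arterial_curve(42, peak_conc=600.0, noise_cv=0.05)
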