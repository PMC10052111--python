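import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dihia import ExposureScenario, KineticParameters, ReconstructionConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def scenario():
    return ExposureScenario()  # 12 weeks, 5 days/week, 8 h/day


@pytest.fixture
def params():
    """Kinetic parameters used throughout the tests (TDI-like half-life)."""
    return KineticParameters(
        absorbed_fraction=0.2,
        ventilation_rate=1.25,
        elimination_half_life=6.0,
        urinary_excretion_fraction=0.1,
        urine_flow=0.0625,
        error_gsd=1.5,
    )


@pytest.fixture
def fast_config():
    return ReconstructionConfig(n_mc=2000, mh_iterations=300, mh_burn_in=100, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12)
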