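import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from progratio import NoiseModel, ParamSet, ratio_progression

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Reference group-mean parameters for sucrose-reinforced, food-deprived rats.
VEHICLE_SUCROSE = ParamSet(t0=3.33, k=0.51, a=23.4, delta=0.21)


@pytest.fixture
def vehicle_params():
    return VEHICLE_SUCROSE


@pytest.fixture
def exp_schedule():
    """The printed 11-term exponential progression."""
    return ratio_progression(11)


@pytest.fixture
def long_schedule():
    """A progression long enough that 40-min sessions end by timeout."""
    return ratio_progression(20)


@pytest.fixture
def no_noise():
    return NoiseModel(pause_cv=0.0, run_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
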