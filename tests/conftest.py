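import pytest
from hypothesis import HealthCheck, settings

from lungscreen import cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Default calibrated 997-patient cohort (seed 1), shared across
    tests since generation is deterministic."""
    return cohort.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def default_cal():
    return cohort.default_calibration()
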