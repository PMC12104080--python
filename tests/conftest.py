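import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-patient default-profile cohort shared across tests."""
    from dgf_kinetics import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_patients=30, seed=11))
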