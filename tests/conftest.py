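import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def timing():
    from rgpt.synchrotron_sim import SynchrotronTiming

    return SynchrotronTiming()


@pytest.fixture(scope="session")
def cohort():
    """Default 5%-scale synthetic cohort, generated once per test session."""
    from rgpt.synthetic_data import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(), seed=1234)
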