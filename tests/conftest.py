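from hypothesis import HealthCheck, settings
import pytest

from poafkit.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-world cohort (n=976) shared across tests."""
    return simulate_cohort(SimulationConfig(n_patients=976, seed=20100101))


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller cohort for structural / pipeline tests."""
    return simulate_cohort(SimulationConfig(n_patients=300, seed=42))
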