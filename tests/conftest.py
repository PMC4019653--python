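import pytest
from hypothesis import HealthCheck, settings

from cdkcycle import default_parameters, simulate_cycles
from cdkcycle.synth import generate_from_model, generate_reference_profiles

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def wt3(params):
    """Three wild-type cycles with the default reset protocol."""
    return simulate_cycles(params, n_cycles=3)


@pytest.fixture(scope="session")
def wt1(params):
    """One wild-type cycle."""
    return simulate_cycles(params, n_cycles=1)


@pytest.fixture(scope="session")
def ref_noiseless():
    """Default synthetic reference dataset, no noise."""
    return generate_reference_profiles(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def model_ds(params):
    """Noiseless dataset generated from the default model."""
    return generate_from_model(params, noise_sd=0.0, seed=0)
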