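import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from methaudit.simulate import (SimulationConfig, generate_reference,
                                sample_beta_matrix, simulate_methylation_profiles)


@pytest.fixture(scope="session")
def demo_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def demo_reference(demo_config):
    return generate_reference(demo_config)


@pytest.fixture(scope="session")
def demo_profiles(demo_config, demo_reference):
    return simulate_methylation_profiles(demo_reference, demo_config)


@pytest.fixture(scope="session")
def demo_betas(demo_config, demo_reference, demo_profiles):
    return sample_beta_matrix(demo_reference, demo_profiles, demo_config)
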