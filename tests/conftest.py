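import pytest

from syntherm import GeneratorConfig, VialSpec, generate_study, generate_timecourse


@pytest.fixture(scope="session")
def vial() -> VialSpec:
    return VialSpec()


@pytest.fixture(scope="session")
def noisefree_study():
    """Noise-free single-replicate runs of all three conditions."""
    return generate_study(seed=11, noise_rel_sd=0.0, n_replicates=1)


@pytest.fixture(scope="session")
def noisy_study():
    """Default triplicate runs with 5% measurement noise."""
    return generate_study(seed=11)


@pytest.fixture()
def noisefree_config() -> GeneratorConfig:
    return GeneratorConfig(condition="5.0", noise_rel_sd=0.0, seed=7)


@pytest.fixture()
def noisefree_timecourses(noisefree_config):
    return generate_timecourse(noisefree_config)
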