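import pytest

from coughphen.synth import SimConfig, gen_corpus, gen_population


@pytest.fixture(scope="session")
def sim_config():
    """Scaled-down study conditions shared across the suite."""
    return SimConfig(seed=11, n_patients=2000, n_notes=300, split_sizes=(180, 60, 60))


@pytest.fixture(scope="session")
def corpus(sim_config):
    return gen_corpus(sim_config)


@pytest.fixture(scope="session")
def population(sim_config):
    return gen_population(sim_config)
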