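import pytest

from tcmlink.synthetic import SyntheticConfig, generate_all, generate_truth


def tiny_config(**overrides) -> SyntheticConfig:
    """Desk-scale world small enough for per-test regeneration."""
    fields = dict(
        n_genes=150,
        n_compounds=4,
        n_diseases=5,
        genes_per_disease=(15, 25),
        signature_size=(20, 30),
        planted_pairs=None,
        noise_sd=0.15,
        seed=7,
    )
    fields.update(overrides)
    return SyntheticConfig(**fields)


@pytest.fixture
def small_config():
    return tiny_config()


@pytest.fixture
def noiseless_config():
    return tiny_config(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """One generated-on-disk synthetic world shared across file-reading tests."""
    outdir = tmp_path_factory.mktemp("world")
    config = tiny_config()
    truth = generate_all(config, outdir)
    return config, truth, outdir


@pytest.fixture(scope="session")
def noiseless_truth():
    config = tiny_config(noise_sd=0.0)
    return config, generate_truth(config)
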