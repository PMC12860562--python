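import pytest

from seasonomics import integration, synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (fixed seed): shared by many tests."""
    return synthetic.simulate(synthetic.SimulationConfig())


@pytest.fixture(scope="session")
def screen_results(default_dataset):
    """End-to-end regulator screen on the default study."""
    return integration.run_regulator_screen(default_dataset)


@pytest.fixture(scope="session")
def small_config():
    """A desk-sized study for tests that re-simulate."""
    return synthetic.SimulationConfig(
        seed=7,
        n_chrom=2,
        chrom_length=200_000,
        bin_size=20_000,
        n_genes=60,
        n_tfs=8,
        n_switch_aab=1,
        n_switch_bab=1,
    )
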