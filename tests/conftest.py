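import numpy as np
import pytest

from hybridpred import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_pollinators=60, n_testers=2, n_pools=3, n_snp=300, n_transcript=120,
        n_metabolite=40, n_causal=60, n_epi_pairs=30, h2=0.7,
        n_locations=2, n_trials=2, n_reps=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_ds(small_config):
    """One fully simulated desk-scale dataset shared across tests."""
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
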