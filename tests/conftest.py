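import numpy as np
import pytest

from hapblup import SimulationConfig, run_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale dataset: 280 individuals, 2 x 150 markers, planted blocks."""
    return SimulationConfig(
        seed=7,
        n_founders=40,
        n_generations=2,
        offspring_per_mating=4,
        n_chromosomes=2,
        markers_per_chromosome=150,
        ld_block_spec=((2, 3), (3, 1), (8, 1)),
        n_qtl=15,
        heritability=0.5,
        n_known_phenotypes=180,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
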