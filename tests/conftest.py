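import numpy as np
import pytest

from circanet.config import ClockGene, SyntheticConfig, default_planted_edges
from circanet.synthetic import generate_compendium


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Scaled-down synthetic universe for fast unit tests."""
    clock = (
        ClockGene("ARNTL", 1.0, 23.0),
        ClockGene("CLOCK", 1.0, 22.0),
        ClockGene("PER1", 1.0, 9.0),
        ClockGene("PER2", 1.0, 10.0),
        ClockGene("PER3", 1.0, 8.0),
        ClockGene("CRY1", 1.0, 12.0),
        ClockGene("CRY2", 1.0, 10.0),
        ClockGene("NR1D1", 1.0, 6.0),
    )
    return SyntheticConfig(
        n_samples=150,
        n_background_genes=200,
        clock_genes=clock,
        planted_edges=default_planted_edges(n_targets=12, clock_genes=clock),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    comp, truth = generate_compendium(small_config)
    return comp, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
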