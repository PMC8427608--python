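import numpy as np
import pandas as pd
import pytest

from indelpop import F2_PANEL, GenotypePanel, SimConfig, simulate_cross, simulate_phenos


@pytest.fixture(scope="session")
def f2_panel() -> GenotypePanel:
    """Published genotype counts of the F2 resource population."""
    return F2_PANEL


@pytest.fixture(scope="session")
def small_cross():
    """A small simulated F2 cross shared across tests (seeded)."""
    config = SimConfig(seed=11, n_f2=350)
    return config, simulate_cross(config)


@pytest.fixture(scope="session")
def small_dataset(small_cross):
    """Phenotypes + genotypes for the small cross."""
    config, cross = small_cross
    phenos = simulate_phenos(cross, config, ["BW2", "CW_carcass", "BSL4"])
    return phenos, cross.genotypes


@pytest.fixture
def genotype_table() -> pd.DataFrame:
    return pd.DataFrame({
        "individual_id": ["a1", "a2", "a3", "a4"],
        "population": ["P", "P", "P", "P"],
        "genotype": ["II", "ID", "DD", pd.NA],
    })


def random_panel(rng: np.random.Generator, max_n: int = 50) -> GenotypePanel:
    """A random genotype panel with at least one individual."""
    n = int(rng.integers(1, max_n + 1))
    counts = rng.multinomial(n, rng.dirichlet([1.0, 1.0, 1.0]))
    return GenotypePanel("rand", *map(int, counts))
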