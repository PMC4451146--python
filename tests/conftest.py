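from pathlib import Path

import numpy as np
import pytest

from lineage_load.pedigree import read_pedigree
from lineage_load.synthetic_data import SimulationConfig, simulate_population

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_path() -> Path:
    return DATA_DIR / "pedigree_15.tsv"


@pytest.fixture(scope="session")
def fixture_pedigree(fixture_path):
    """15-person, 4-generation pedigree: one proband with a complete
    ancestor lattice (father age 25, grandfathers 30/35, great-grandfathers
    all 40)."""
    return read_pedigree(fixture_path)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated population shared across read-only tests."""
    config = SimulationConfig(n_founder_couples=120, n_generations=5, seed=20240)
    return simulate_population(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(991)
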