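from pathlib import Path

import pytest

from xylemtraits import derive_all
from xylemtraits.synthetic import SimulationConfig, simulate_dataset, simulate_tree

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def dataset():
    """Full-size synthetic study: 17 species x 10 individuals, 50 tracheids."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def derived(dataset):
    return derive_all(dataset.anatomy)


@pytest.fixture(scope="session")
def tree50():
    return simulate_tree(50, seed=11)


@pytest.fixture(scope="session")
def fixtures_dir():
    return FIXTURES
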