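import numpy as np
import pytest
from hypothesis import settings

from famsubtype.reference_rates import RateCell, RateTable
from famsubtype.synthetic_data import simulate_rate_table

settings.register_profile("suite", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def single_cell_table() -> RateTable:
    """One cell, ages [50,55) x [1990,1995), rate 2.5e-3 per woman-year."""
    return RateTable([RateCell(50, 55, 1990, 1995, 2.5e-3)])


@pytest.fixture(scope="session")
def grid_table() -> RateTable:
    """Synthetic breast-cancer-like grid: ages 0-85, periods 1960-2010."""
    return simulate_rate_table()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20100210)
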