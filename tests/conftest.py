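import numpy as np
import pytest

from ephah.spectra import SpectraSet, WavenumberGrid
from ephah.synthetic import SimulationConfig, simulate_spectra

#: compact grid covering the same 4000–12,000 cm⁻¹ span as the instrument
#: convention, used wherever full 2074-point resolution is unnecessary
SMALL_GRID = WavenumberGrid(start=4000.0, step=16.0, n_points=500)
TINY_GRID = WavenumberGrid(start=4000.0, step=40.0, n_points=200)


@pytest.fixture(scope="session")
def small_grid() -> WavenumberGrid:
    return SMALL_GRID


@pytest.fixture(scope="session")
def tiny_grid() -> WavenumberGrid:
    return TINY_GRID


@pytest.fixture(scope="session")
def spectra_3class(tiny_grid) -> SpectraSet:
    """Well-separated 3-class set for classifier smoke tests."""
    cfg = SimulationConfig(grid=tiny_grid, n_classes=3,
                           samples_per_class=(15, 15, 15),
                           class_separation=0.1, seed=11)
    return simulate_spectra(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
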