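import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from corridorscape import LandscapeConfig, Raster, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """A compact landscape: fast to generate, rich enough for every stage."""
    return LandscapeConfig(grid_rows=120, grid_cols=120, n_reserves=14,
                           n_kbas=5, n_countries=3, seed=5)


@pytest.fixture(scope="session")
def small_scape(small_config):
    return generate_landscape(small_config)


@pytest.fixture
def flat_raster():
    """Factory for uniform-valued rasters."""

    def make(value: float, shape=(10, 10), cell=100.0) -> Raster:
        return Raster(np.full(shape, float(value)), cell_size=cell)

    return make
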