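import numpy as np
import pytest

from refugia.grid import RasterGrid, Transform
from refugia.synthetic import (
    LandscapeConfig,
    default_niches,
    generate_landscape,
    register_truth,
    sample_all_occurrences,
)


@pytest.fixture
def small_grid():
    """5x5 all-valid grid around 86-87E / 47-48N."""
    rng = np.random.default_rng(7)
    return RasterGrid(rng.random((5, 5)), Transform(86.0, 48.0, 0.2))


@pytest.fixture(scope="session")
def small_landscape():
    """A compact synthetic basin shared by read-only tests."""
    cfg = LandscapeConfig(n_rows=48, n_cols=48, cell_size_deg=0.025, seed=11, n_species=6)
    landscape = generate_landscape(cfg)
    specs = default_niches(landscape, seed=11)
    register_truth(landscape, specs)
    occ = sample_all_occurrences(landscape, specs, seed=11)
    return landscape, specs, occ
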