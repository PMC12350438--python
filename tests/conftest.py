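import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from seqlcp import CostRaster, GridTransform


@pytest.fixture
def transform() -> GridTransform:
    return GridTransform(x_origin=0.0, y_origin=100_000.0,
                         cell_width=10_000.0, cell_height=10_000.0)


@pytest.fixture
def uniform_cost(transform) -> CostRaster:
    """10x10 grid, every cell cost 1.0."""
    return CostRaster(values=np.ones((10, 10)), transform=transform,
                      crs_id="SYNTH:EQD")


def random_cost_raster(rng: np.random.Generator, nrows: int, ncols: int,
                       p_nodata: float = 0.15) -> CostRaster:
    """Random costs in [0, 1] with random impassable cells."""
    vals = rng.uniform(0.0, 1.0, size=(nrows, ncols))
    vals[rng.uniform(size=(nrows, ncols)) < p_nodata] = np.inf
    t = GridTransform(0.0, nrows * 10_000.0, 10_000.0, 10_000.0)
    return CostRaster(values=vals, transform=t, crs_id="SYNTH:EQD")
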