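"""Convert a habitat-suitability raster into a traversal-cost surface.

Builds a tiny suitability grid, writes it as an ESRI ASCII grid, and loads
it back in "suitability" mode: values are inverted and rescaled to [0, 1]
(high suitability -> low cost) and NoData cells become impassable (+inf).
"""

import tempfile
from pathlib import Path

import numpy as np

from seqlcp import GridTransform, Raster, load_cost, write_ascii_grid

# suitability in arbitrary model units; one NoData cell plays the ocean
suit = np.array([
    [120.0, 300.0, 500.0],
    [80.0, -9999.0, 700.0],
    [60.0, 450.0, 900.0],
])
raster = Raster(
    values=suit,
    transform=GridTransform(0.0, 30_000.0, 10_000.0, 10_000.0),
    nodata=-9999.0,
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "suitability.asc"
    write_ascii_grid(raster, path)
    cost = load_cost(path, mode="suitability")

print("suitability grid:")
print(suit)
print("\ncost surface (0 = most permeable, 1 = least, inf = barrier):")
print(np.round(cost.values, 3))
print(
    "\nThe most suitable cell (900) became cost 0, the least suitable (60)"
    "\ncost 1, and the NoData cell is an impassable barrier for path tracing."
)
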