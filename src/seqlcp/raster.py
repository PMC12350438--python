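"""Cost-surface preparation: raster container, suitability-to-cost inversion, ASCII grid I/O.

A cost surface (resistance surface) is a raster grid in a projected,
equal-distance CRS where each cell value quantifies the difficulty of
moving through that cell.  Habitat-suitability maps are converted to cost
by inverting and rescaling to [0, 1], so that high suitability means low
traversal cost.  NoData cells (for example ocean) become infinitely costly
and therefore act as impassable barriers.

Rasters are read and written as plain-text ESRI ASCII grids (``.asc``),
single band, square cells, north-up.  Inputs are assumed to be already
projected and resampled; no reprojection is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GridTransform",
    "Raster",
    "CostRaster",
    "invert_rescale",
    "load_cost",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_cost",
]

#: CRS identifiers known to be geographic (degrees); cost-distance analysis
#: requires a projected CRS with metric coordinates.
_GEOGRAPHIC_CRS_IDS = frozenset({
    "EPSG:4326", "EPSG:4258", "EPSG:4269", "EPSG:4267", "EPSG:4230",
    "CRS84", "OGC:CRS84", "WGS84",
})


def _is_geographic(crs_id: str | None) -> bool:
    if crs_id is None:
        return False
    cid = crs_id.strip()
    return cid.upper() in _GEOGRAPHIC_CRS_IDS or "+proj=longlat" in cid


@dataclass(frozen=True)
class GridTransform:
    """North-up affine mapping between cell indices and projected coordinates.

    Rows increase downward, columns rightward, both 0-based.  ``x_origin``
    and ``y_origin`` are the coordinates of the outer corner of cell (0, 0)
    (west edge, north edge).  Cells are half-open: a point on a shared edge
    belongs to the cell to its right / below in index space.
    """

    x_origin: float
    y_origin: float
    cell_width: float
    cell_height: float

    def __post_init__(self) -> None:
        if self.cell_width <= 0 or self.cell_height <= 0:
            raise ValueError("cell width and height must be strictly positive")

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return the (row, col) of the cell containing the point (x, y)."""
        col = math.floor((x - self.x_origin) / self.cell_width)
        row = math.floor((self.y_origin - y) / self.cell_height)
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """Return the projected coordinates of the center of cell (row, col)."""
        x = self.x_origin + (col + 0.5) * self.cell_width
        y = self.y_origin - (row + 0.5) * self.cell_height
        return x, y


@dataclass(frozen=True)
class Raster:
    """A single-band raster: 2-D value grid plus georeferencing.

    ``values`` is row-major with row 0 at the top.  ``nodata`` is the
    sentinel marking cells without data; ``None`` means fully valid.
    """

    values: np.ndarray
    transform: GridTransform
    crs_id: str | None = None
    nodata: float | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid (single band)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nodata_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.zeros(self.shape, dtype=bool)
        if np.isnan(self.nodata):
            return np.isnan(self.values)
        return self.values == self.nodata


@dataclass(frozen=True)
class CostRaster:
    """Analysis-ready traversal-cost grid.

    Finite values are per-cell costs (in [0, 1] after standard preparation,
    unbounded if the user supplied a pre-made cost raster).  Impassable
    cells are exactly +inf and correspond to NoData in the source.
    A cost of exactly 0 is legal (a zero-cost corridor); accumulated path
    costs may then be 0 over nonzero distances.
    """

    values: np.ndarray
    transform: GridTransform
    crs_id: str | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("cost values must be a 2-D grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("traversal costs must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def passable(self) -> np.ndarray:
        """Boolean mask of traversable cells (finite cost)."""
        return np.isfinite(self.values)

    def in_bounds(self, row: int, col: int) -> bool:
        nr, nc = self.shape
        return 0 <= row < nr and 0 <= col < nc


def invert_rescale(
    suitability: Raster,
    vmin: float | None = None,
    vmax: float | None = None,
) -> CostRaster:
    """Convert a suitability raster to cost by inversion and rescaling.

    Each finite value ``v`` maps to ``(vmax - v) / (vmax - vmin)`` so that
    maximum suitability becomes cost 0 and minimum suitability cost 1.
    ``vmin``/``vmax`` default to the observed finite range of the raster.
    NoData cells map to +inf (impassable).

    Raises ``ValueError`` on a degenerate range or, when bounds are
    user-supplied, on finite values outside [vmin, vmax].
    """
    mask = suitability.nodata_mask()
    vals = np.asarray(suitability.values, dtype=float)
    finite = vals[~mask & np.isfinite(vals)]
    user_bounds = vmin is not None or vmax is not None
    if vmin is None:
        if finite.size == 0:
            raise ValueError("raster has no finite data values")
        vmin = float(finite.min())
    if vmax is None:
        if finite.size == 0:
            raise ValueError("raster has no finite data values")
        vmax = float(finite.max())
    if vmax <= vmin:
        raise ValueError(
            f"degenerate value range: vmin={vmin!r}, vmax={vmax!r} (need vmax > vmin)"
        )
    if user_bounds and finite.size:
        lo, hi = float(finite.min()), float(finite.max())
        if lo < vmin or hi > vmax:
            bad = lo if lo < vmin else hi
            raise ValueError(
                f"value {bad!r} outside the supplied range [{vmin!r}, {vmax!r}]"
            )
    cost = (vmax - vals) / (vmax - vmin)
    cost[mask | ~np.isfinite(vals)] = np.inf
    return CostRaster(values=cost, transform=suitability.transform, crs_id=suitability.crs_id)


def read_ascii_grid(path: str | Path, crs_id: str | None = None) -> Raster:
    """Read a single-band ESRI ASCII grid (.asc).

    Recognises the standard header keys (ncols, nrows, xllcorner/xllcenter,
    yllcorner/yllcenter, cellsize, nodata_value).  The optional ``crs_id``
    attaches a CRS identifier, since the format itself carries none.
    """
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols", "nrows", "xllcorner", "yllcorner",
                "xllcenter", "yllcenter", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: ASCII grid header missing '{req}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    if "xllcorner" in header:
        xll = header["xllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - cellsize / 2
    else:
        raise ValueError(f"{path}: ASCII grid header missing xllcorner/xllcenter")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - cellsize / 2
    else:
        raise ValueError(f"{path}: ASCII grid header missing yllcorner/yllcenter")
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    transform = GridTransform(
        x_origin=xll,
        y_origin=yll + nrows * cellsize,
        cell_width=cellsize,
        cell_height=cellsize,
    )
    nodata = header.get("nodata_value")
    return Raster(values=values, transform=transform, crs_id=crs_id, nodata=nodata)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid with full float precision."""
    t = raster.transform
    if t.cell_width != t.cell_height:
        raise ValueError("ASCII grids require square cells")
    nrows, ncols = raster.shape
    nodata = raster.nodata if raster.nodata is not None else -9999.0
    vals = np.asarray(raster.values, dtype=float)
    with Path(path).open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {t.x_origin!r}\n")
        fh.write(f"yllcorner {t.y_origin - nrows * t.cell_height!r}\n")
        fh.write(f"cellsize {t.cell_width!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def write_cost(cost: CostRaster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a cost raster to an ASCII grid, encoding +inf cells as nodata."""
    vals = cost.values.copy()
    vals[~np.isfinite(vals)] = nodata
    write_ascii_grid(
        Raster(values=vals, transform=cost.transform, crs_id=cost.crs_id, nodata=nodata),
        path,
    )


def load_cost(
    raster_path: str | Path,
    mode: str = "suitability",
    crs_id: str | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
) -> CostRaster:
    """Load a raster file as an analysis-ready cost surface.

    mode "suitability" applies :func:`invert_rescale` (observed range unless
    ``vmin``/``vmax`` are given); mode "cost" passes finite values through
    unchanged.  NoData becomes +inf in both modes.  A known-geographic CRS
    identifier is rejected: the analysis needs metric, equal-distance
    coordinates.
    """
    if mode not in ("suitability", "cost"):
        raise ValueError(f"mode must be 'suitability' or 'cost', got {mode!r}")
    if _is_geographic(crs_id):
        raise ValueError(
            f"CRS {crs_id!r} is geographic (degrees); supply data in a projected "
            "equal-distance CRS (meters)"
        )
    raster = read_ascii_grid(raster_path, crs_id=crs_id)
    if mode == "suitability":
        return invert_rescale(raster, vmin=vmin, vmax=vmax)
    vals = np.asarray(raster.values, dtype=float).copy()
    vals[raster.nodata_mask() | ~np.isfinite(vals)] = np.inf
    return CostRaster(values=vals, transform=raster.transform, crs_id=crs_id)
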