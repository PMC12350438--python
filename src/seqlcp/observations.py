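"""Occurrence records: reading, snapping to raster cells, per-cell deduplication.

Occurrence records of the invading species are points (id, x, y, year) in
the projected CRS of the cost surface.  The path-finding algorithm operates
at the resolution of the cost surface, so records are snapped to cells and
reduced to one record per cell, retaining the earliest observation year —
this avoids duplicated and zero-length paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import CostRaster

__all__ = [
    "ObservationRecord",
    "CellRecord",
    "read_observations",
    "snap",
    "dedupe",
    "filter_isolated",
    "write_cell_records",
]

YEAR_RANGE = (1900, 2100)


@dataclass(frozen=True)
class ObservationRecord:
    """A raw occurrence record in projected coordinates (meters)."""

    record_id: str
    x: float
    y: float
    year: int
    label: str | None = None  # optional country/region attribute for naming

    def __post_init__(self) -> None:
        lo, hi = YEAR_RANGE
        if not lo <= self.year <= hi:
            raise ValueError(
                f"record {self.record_id!r}: year {self.year} outside plausible "
                f"range [{lo}, {hi}]"
            )


@dataclass
class CellRecord:
    """One occupied raster cell: earliest year and the member records snapped to it.

    ``passable`` is False for cells that are NoData/impassable on the cost
    surface; such records are kept but can never be path endpoints and end
    up unassigned.
    """

    row: int
    col: int
    year: int
    member_ids: list[str] = field(default_factory=list)
    passable: bool = True

    @property
    def cell(self) -> tuple[int, int]:
        return (self.row, self.col)


def read_observations(path: str | Path) -> list[ObservationRecord]:
    """Read records from a CSV with required columns id,x,y,year.

    An optional ``country`` (or ``label``) column is carried along for
    population naming.
    """
    df = pd.read_csv(path)
    required = {"id", "x", "y", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    label_col = "country" if "country" in df.columns else (
        "label" if "label" in df.columns else None
    )
    records = []
    for tup in df.itertuples(index=False):
        label = getattr(tup, label_col) if label_col else None
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        records.append(
            ObservationRecord(
                record_id=str(tup.id),
                x=float(tup.x),
                y=float(tup.y),
                year=int(tup.year),
                label=None if label is None else str(label),
            )
        )
    return records


def snap(
    records: list[ObservationRecord], cost: CostRaster
) -> dict[str, tuple[int, int]]:
    """Map each record to the (row, col) of the cell containing its point.

    Cells are half-open: a point on a shared edge belongs to the cell to
    its right / below.  Raises ``ValueError`` listing the ids of any
    records outside the raster bounds.
    """
    mapping: dict[str, tuple[int, int]] = {}
    out_of_bounds: list[str] = []
    for rec in records:
        row, col = cost.transform.cell_of(rec.x, rec.y)
        if not cost.in_bounds(row, col):
            out_of_bounds.append(rec.record_id)
        else:
            mapping[rec.record_id] = (row, col)
    if out_of_bounds:
        raise ValueError(
            f"{len(out_of_bounds)} record(s) outside raster bounds: "
            f"{out_of_bounds[:20]}"
        )
    return mapping


def dedupe(
    records: list[ObservationRecord],
    snapping: dict[str, tuple[int, int]],
    cost: CostRaster | None = None,
) -> list[CellRecord]:
    """Reduce records to one CellRecord per occupied cell with the earliest year.

    member_ids keep input order and partition the input record ids.  If a
    cost raster is given, records snapped to impassable cells are flagged
    (``passable=False``) rather than dropped.
    """
    by_cell: dict[tuple[int, int], CellRecord] = {}
    for rec in records:
        cell = snapping[rec.record_id]
        cr = by_cell.get(cell)
        if cr is None:
            passable = True
            if cost is not None:
                passable = bool(np.isfinite(cost.values[cell]))
            by_cell[cell] = CellRecord(
                row=cell[0], col=cell[1], year=rec.year,
                member_ids=[rec.record_id], passable=passable,
            )
        else:
            cr.member_ids.append(rec.record_id)
            cr.year = min(cr.year, rec.year)
    return list(by_cell.values())


def filter_isolated(
    records: list[ObservationRecord], max_isolation_km: float
) -> tuple[list[ObservationRecord], list[ObservationRecord]]:
    """Drop records farther than ``max_isolation_km`` from any other record.

    Optional pre-filter for extreme outliers (for example single remote
    citizen-science records hundreds of km from the invasion front).
    Returns (kept, dropped).
    """
    if len(records) < 2:
        return list(records), []
    xy = np.array([(r.x, r.y) for r in records])
    tree = cKDTree(xy)
    # nearest neighbour other than self
    dists, _ = tree.query(xy, k=2)
    nn_m = dists[:, 1]
    keep_mask = nn_m <= max_isolation_km * 1000.0
    kept = [r for r, k in zip(records, keep_mask) if k]
    dropped = [r for r, k in zip(records, keep_mask) if not k]
    return kept, dropped


def write_cell_records(cell_records: list[CellRecord], path: str | Path) -> None:
    """Write cell records as CSV with columns row,col,year,n_members,passable."""
    df = pd.DataFrame(
        {
            "row": [c.row for c in cell_records],
            "col": [c.col for c in cell_records],
            "year": [c.year for c in cell_records],
            "n_members": [len(c.member_ids) for c in cell_records],
            "passable": [c.passable for c in cell_records],
        }
    )
    df.to_csv(path, index=False)
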