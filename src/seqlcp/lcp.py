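"""Sequential least-cost path engine on an 8-connected grid graph.

The landscape raster is treated as a graph whose nodes are passable cells
and whose edges connect 8-neighbours.  Moving between adjacent cells costs
the mean of the two cell costs, weighted by the geometric step length
(1 for orthogonal, sqrt(2) for diagonal moves, in cell units) — so
accumulated costs are dimensionless "cost x cell" quantities.  Impassable
(+inf) cells act as absolute barriers.

The sequential model iterates calendar years in ascending order.  For each
year t, a multi-source shortest-path (Dijkstra) accumulation is run from
all cells observed before t, and one least-cost path is traced back for
each cell newly observed in t.  The union of all paths over all years is
the dispersal network, kept unfiltered (including extremely high-cost
paths) for downstream thresholding.

Determinism: when several optimal predecessors exist, the traceback takes
the neighbour with the smallest (row, col) lexicographic index, so path
geometries are reproducible and independent of record input order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .observations import CellRecord
from .raster import CostRaster, GridTransform

__all__ = [
    "LeastCostPath",
    "SequentialResult",
    "step_cost",
    "accumulate",
    "trace_path",
    "trace_year",
    "run_sequential",
]

SQRT2 = math.sqrt(2.0)

# 8-neighbourhood offsets with geometric step lengths (cell units)
_NEIGHBORS: tuple[tuple[int, int, float], ...] = (
    (-1, -1, SQRT2), (-1, 0, 1.0), (-1, 1, SQRT2),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, SQRT2), (1, 0, 1.0), (1, 1, SQRT2),
)


@dataclass(frozen=True)
class LeastCostPath:
    """A least-cost path from an earlier record (source) to a new record (target).

    ``cells`` runs from source to target; consecutive cells are
    8-neighbours.  ``accumulated_cost`` is the sum of geometric step costs
    along the path (dimensionless, cost x cell units).  ``year`` is the
    target's observation year, i.e. the time step that created the path.
    """

    source: tuple[int, int]
    target: tuple[int, int]
    year: int
    accumulated_cost: float
    cells: tuple[tuple[int, int], ...]

    def line_coordinates(self, transform: GridTransform) -> list[tuple[float, float]]:
        """Path geometry as projected cell-center coordinates."""
        return [transform.center_of(r, c) for r, c in self.cells]


@dataclass
class SequentialResult:
    """Outcome of the sequential tracing: the dispersal network plus leftovers."""

    paths: list[LeastCostPath]
    seeds: list[CellRecord]
    isolated: list[CellRecord] = field(default_factory=list)


def step_cost(cost_a: float, cost_b: float, move: str) -> float:
    """Geometric cost of one move between adjacent cells.

    Returns ``L * (cost_a + cost_b) / 2`` with L = 1 for "orthogonal" and
    sqrt(2) for "diagonal" moves; +inf if either cell is impassable.
    """
    if cost_a < 0 or cost_b < 0:
        raise ValueError("cell costs must be non-negative")
    if move == "orthogonal":
        length = 1.0
    elif move == "diagonal":
        length = SQRT2
    else:
        raise ValueError(f"move must be 'orthogonal' or 'diagonal', got {move!r}")
    return length * (cost_a + cost_b) / 2.0


def accumulate(
    cost: CostRaster, sources: set[tuple[int, int]] | list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source cost-distance accumulation over the 8-connected grid.

    Runs Dijkstra's algorithm from all source cells simultaneously.
    Returns ``(cost_distance, traceback)`` where ``cost_distance[r, c]`` is
    the minimum accumulated cost from any source to cell (r, c) (+inf if
    unreachable, 0 at sources) and ``traceback`` holds the flattened index
    of the optimal predecessor (-1 at sources and unreachable cells).

    Ties between optimal predecessors resolve to the smallest (row, col)
    lexicographic index, making tracebacks deterministic.
    """
    vals = cost.values
    nrows, ncols = vals.shape
    src = [s for s in sources if np.isfinite(vals[s])]
    if not src:
        raise ValueError("no passable source cells")

    dist = np.full((nrows, ncols), np.inf)
    pred = np.full((nrows, ncols), -1, dtype=np.int64)
    visited = np.zeros((nrows, ncols), dtype=bool)

    heap: list[tuple[float, int, int]] = []
    for r, c in src:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))

    while heap:
        d, r, c = heapq.heappop(heap)
        if visited[r, c] or d > dist[r, c]:
            continue
        visited[r, c] = True
        here = vals[r, c]
        for dr, dc, length in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols):
                continue
            other = vals[nr, nc]
            if not np.isfinite(other) or visited[nr, nc]:
                continue
            nd = d + length * (here + other) / 2.0
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                pred[nr, nc] = r * ncols + c
                heapq.heappush(heap, (nd, nr, nc))
            elif nd == dist[nr, nc] and pred[nr, nc] >= 0:
                # equal-cost predecessor: keep the lexicographically smallest
                if r * ncols + c < pred[nr, nc]:
                    pred[nr, nc] = r * ncols + c
    return dist, pred


def trace_path(
    traceback: np.ndarray, target: tuple[int, int]
) -> tuple[tuple[int, int], ...]:
    """Reconstruct one optimal path from a source to ``target``.

    Returns the cell sequence source -> target.  The target must have been
    reached by the accumulation (or be a source itself).
    """
    ncols = traceback.shape[1]
    cells = [target]
    r, c = target
    while traceback[r, c] >= 0:
        p = int(traceback[r, c])
        r, c = divmod(p, ncols)
        cells.append((r, c))
        if len(cells) > traceback.size:
            raise RuntimeError("traceback cycle detected")
    cells.reverse()
    return tuple(cells)


def trace_year(
    cost: CostRaster,
    known: list[CellRecord],
    new: list[CellRecord],
    year: int,
) -> tuple[list[LeastCostPath], list[CellRecord]]:
    """Trace one least-cost path per new record back to the nearest known record.

    ``known`` must all predate ``year``; ``new`` records all carry
    ``year``.  Records on impassable cells or cut off by barriers yield no
    path and are returned in the isolated list — unreachability is a
    reported outcome, not an error.
    """
    for rec in known:
        if rec.year >= year:
            raise ValueError(f"known record in cell {rec.cell} has year {rec.year} >= {year}")
    for rec in new:
        if rec.year != year:
            raise ValueError(f"new record in cell {rec.cell} has year {rec.year} != {year}")
    sources = [rec.cell for rec in known if rec.passable]
    if not sources:
        raise ValueError("no passable source cells among known records")
    dist, pred = accumulate(cost, sources)
    paths: list[LeastCostPath] = []
    isolated: list[CellRecord] = []
    for rec in sorted(new, key=lambda r: r.cell):
        if not rec.passable or not np.isfinite(dist[rec.cell]):
            isolated.append(rec)
            continue
        cells = trace_path(pred, rec.cell)
        paths.append(
            LeastCostPath(
                source=cells[0],
                target=rec.cell,
                year=year,
                accumulated_cost=float(dist[rec.cell]),
                cells=cells,
            )
        )
    return paths, isolated


def run_sequential(
    cost: CostRaster,
    cell_records: list[CellRecord],
    chain_within_year: bool = False,
) -> SequentialResult:
    """Run the annual sequential least-cost model over all cell records.

    Years are iterated in ascending order; in year t the sources are all
    records observed before t and the targets those observed in t.  All
    records sharing the global earliest year are seeds and receive no
    incoming path.  With ``chain_within_year=True`` each traced target
    immediately becomes a source for the remaining targets of the same
    year (an alternative reading of "previously known"; the default links
    strictly earlier years only and is order-independent).

    Returns the full dispersal network, including extremely high-cost
    paths — filtering happens downstream at delineation time.
    """
    if not cell_records:
        raise ValueError("no cell records supplied")
    years = sorted({rec.year for rec in cell_records})
    first_year = years[0]
    seeds = [rec for rec in cell_records if rec.year == first_year]
    paths: list[LeastCostPath] = []
    isolated: list[CellRecord] = []
    known = list(seeds)
    for year in years[1:]:
        new = [rec for rec in cell_records if rec.year == year]
        if not chain_within_year:
            p, iso = trace_year(cost, known, new, year)
            paths.extend(p)
            isolated.extend(iso)
        else:
            # each traced target immediately becomes a source for the
            # remaining same-year targets (processed in deterministic
            # (row, col) order)
            for rec in sorted(new, key=lambda r: r.cell):
                sources = [k.cell for k in known if k.passable]
                if not rec.passable:
                    isolated.append(rec)
                else:
                    dist, pred = accumulate(cost, sources)
                    if not np.isfinite(dist[rec.cell]):
                        isolated.append(rec)
                    else:
                        cells = trace_path(pred, rec.cell)
                        paths.append(LeastCostPath(
                            source=cells[0], target=rec.cell, year=year,
                            accumulated_cost=float(dist[rec.cell]), cells=cells,
                        ))
                known.append(rec)
        if not chain_within_year:
            known.extend(new)
    return SequentialResult(paths=paths, seeds=seeds, isolated=isolated)
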