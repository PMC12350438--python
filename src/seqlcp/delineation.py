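"""Population delineation from the dispersal network.

Four steps: (1) least-cost paths whose accumulated cost exceeds a threshold
are removed — the threshold plays the role of the species' maximum yearly
dispersal capacity in cost-distance units; (2) the remaining paths are
grouped into populations by connectivity, where two paths belong together
iff they share an endpoint cell (connected components of the endpoint
graph); (3) observation records are assigned to the population of any
retained path starting or ending in their cell — records isolated by
barriers or by path removal stay unassigned; (4) each population's
spatio-temporal data coverage is summarised as the median raw-observation
count per calendar year (zero-filling silent years), and populations at or
above a coverage threshold are classified robust, the rest sparse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .lcp import LeastCostPath
from .observations import CellRecord, ObservationRecord

__all__ = [
    "UNASSIGNED",
    "PopulationPartition",
    "quantile_of_threshold",
    "threshold_of_quantile",
    "filter_paths",
    "components",
    "assign_records",
    "classify",
    "delineate",
]

#: Sentinel population id for records no retained path touches.
UNASSIGNED = -1


@dataclass
class PopulationPartition:
    """Assignment of paths and records to populations.

    ``path_population`` maps each retained path (by identity in the
    retained list) to a population id; ``record_population`` maps raw
    record ids to a population id or :data:`UNASSIGNED`; ``populations``
    is a table with one row per population (name, first/latest year,
    record count, median observations per year, robust/sparse status).
    """

    retained_paths: list[LeastCostPath]
    path_population: dict[int, int]          # index into retained_paths -> pop id
    record_population: dict[str, int]        # record_id -> pop id or UNASSIGNED
    populations: pd.DataFrame

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for p in self.record_population.values() if p == UNASSIGNED)


def _costs(paths: list[LeastCostPath]) -> np.ndarray:
    return np.array([p.accumulated_cost for p in paths], dtype=float)


def quantile_of_threshold(paths: list[LeastCostPath], threshold: float) -> float:
    """Empirical-CDF fraction of paths with accumulated cost <= threshold."""
    if not paths:
        raise ValueError("empty path set")
    return float(np.mean(_costs(paths) <= threshold))


def threshold_of_quantile(paths: list[LeastCostPath], q: float) -> float:
    """Smallest path cost c with an empirical-CDF fraction >= q.

    No interpolation: the returned value is always an observed path cost
    (q = 1 gives the maximum).
    """
    if not paths:
        raise ValueError("empty path set")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {q!r}")
    costs = np.sort(_costs(paths))
    k = max(int(np.ceil(q * costs.size)), 1)
    return float(costs[k - 1])


def filter_paths(paths: list[LeastCostPath], threshold: float) -> list[LeastCostPath]:
    """Retain exactly the paths with accumulated cost <= threshold.

    Paths at exactly the threshold are kept ("exceeded" means strictly
    greater).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return [p for p in paths if p.accumulated_cost <= threshold]


def components(retained_paths: list[LeastCostPath]) -> dict[int, int]:
    """Group retained paths into populations by shared endpoint cells.

    Builds the undirected graph whose nodes are path endpoint cells and
    whose edges are the paths, and labels its connected components.
    Population ids are assigned deterministically: components are ordered
    by earliest member path year, then by smallest endpoint (row, col).
    Returns a map from path index (into ``retained_paths``) to id.
    """
    if not retained_paths:
        return {}
    nodes: dict[tuple[int, int], int] = {}
    for p in retained_paths:
        for cell in (p.source, p.target):
            if cell not in nodes:
                nodes[cell] = len(nodes)
    n = len(nodes)
    rows = [nodes[p.source] for p in retained_paths]
    cols = [nodes[p.target] for p in retained_paths]
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = _cc(graph, directed=False)

    # deterministic relabelling: by earliest path year, then smallest endpoint
    comp_year: dict[int, int] = {}
    comp_cell: dict[int, tuple[int, int]] = {}
    for p in retained_paths:
        lab = int(labels[nodes[p.source]])
        comp_year[lab] = min(comp_year.get(lab, p.year), p.year)
        best = min(p.source, p.target)
        comp_cell[lab] = min(comp_cell.get(lab, best), best)
    order = sorted(comp_year, key=lambda lab: (comp_year[lab], comp_cell[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(order)}
    return {
        i: relabel[int(labels[nodes[p.source]])]
        for i, p in enumerate(retained_paths)
    }


def assign_records(
    cell_records: list[CellRecord],
    retained_paths: list[LeastCostPath],
    path_population: dict[int, int],
) -> dict[str, int]:
    """Assign raw records to populations through their cells.

    A record receives the population of any retained path with an endpoint
    in its snapped cell; raw (pre-dedup) records inherit the assignment of
    their cell.  Records in cells touched by no retained path endpoint map
    to :data:`UNASSIGNED`.
    """
    cell_pop: dict[tuple[int, int], int] = {}
    for i, p in enumerate(retained_paths):
        pop = path_population[i]
        for cell in (p.source, p.target):
            prev = cell_pop.get(cell)
            if prev is not None and prev != pop:
                raise AssertionError(
                    f"cell {cell} touched by endpoints of populations {prev} and "
                    f"{pop}; connectivity components must make this impossible"
                )
            cell_pop[cell] = pop
    out: dict[str, int] = {}
    for cr in cell_records:
        pop = cell_pop.get(cr.cell, UNASSIGNED)
        for rid in cr.member_ids:
            out[rid] = pop
    return out


def _population_names(
    pop_meta: pd.DataFrame, labels: dict[int, str | None]
) -> dict[int, str]:
    """Build "<label> <first_year>" names with a/b/c suffixes on collision.

    Collisions are suffixed in order of descending record count, then
    descending latest year, then population id.
    """
    base: dict[int, str] = {}
    for pid, row in pop_meta.iterrows():
        label = labels.get(pid) or f"pop{pid}"
        base[pid] = f"{label} {int(row.first_year)}"
    names: dict[int, str] = {}
    groups: dict[str, list[int]] = {}
    for pid, b in base.items():
        groups.setdefault(b, []).append(pid)
    for b, pids in groups.items():
        if len(pids) == 1:
            names[pids[0]] = b
        else:
            ordered = sorted(
                pids,
                key=lambda p: (-pop_meta.loc[p, "n_records"],
                               -pop_meta.loc[p, "latest_year"], p),
            )
            for i, pid in enumerate(ordered):
                names[pid] = f"{b}{chr(ord('a') + i)}"
    return names


def classify(
    records: list[ObservationRecord],
    record_population: dict[str, int],
    robust_threshold: float = 10.0,
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Summarise populations and classify them as robust or sparse.

    For each population, raw-record counts are computed per calendar year
    over [first_year, latest_year]; with ``zero_fill`` (default) years
    without records count as zero, penalising gaps in temporal coverage.
    A population is robust iff the median count >= ``robust_threshold``
    (a median exactly at the threshold counts as robust).

    Returns a table indexed by population id with columns name,
    first_year, latest_year, n_records, median_per_year, status, sorted by
    (first_year asc, latest_year desc, id).
    """
    if robust_threshold <= 0:
        raise ValueError("robust threshold must be positive")
    by_pop: dict[int, list[ObservationRecord]] = {}
    for rec in records:
        pop = record_population.get(rec.record_id, UNASSIGNED)
        if pop != UNASSIGNED:
            by_pop.setdefault(pop, []).append(rec)
    rows = []
    labels: dict[int, str | None] = {}
    for pid, members in by_pop.items():
        years = np.array([m.year for m in members])
        first, latest = int(years.min()), int(years.max())
        if zero_fill:
            span = np.arange(first, latest + 1)
            counts = np.array([(years == y).sum() for y in span])
        else:
            counts = np.unique(years, return_counts=True)[1]
        median = float(np.median(counts))
        earliest = min(members, key=lambda m: m.year)
        labels[pid] = earliest.label
        rows.append(
            dict(population_id=pid, first_year=first, latest_year=latest,
                 n_records=len(members), median_per_year=median,
                 status="robust" if median >= robust_threshold else "sparse")
        )
    if not rows:
        return pd.DataFrame(
            columns=["name", "first_year", "latest_year", "n_records",
                     "median_per_year", "status"]
        )
    df = pd.DataFrame(rows).set_index("population_id")
    names = _population_names(df, labels)
    df.insert(0, "name", [names[p] for p in df.index])
    return df.sort_values(
        ["first_year", "latest_year"], ascending=[True, False], kind="stable"
    )


def delineate(
    paths: list[LeastCostPath],
    cell_records: list[CellRecord],
    records: list[ObservationRecord],
    threshold: float | None = None,
    quantile: float | None = None,
    robust_threshold: float = 10.0,
    zero_fill: bool = True,
) -> PopulationPartition:
    """Run the full four-step delineation at one operating point.

    Exactly one of ``threshold`` (accumulated-cost units) or ``quantile``
    (fraction of paths to retain, converted through the empirical CDF)
    must be given.
    """
    if (threshold is None) == (quantile is None):
        raise ValueError("exactly one of threshold/quantile must be set")
    if threshold is None:
        threshold = threshold_of_quantile(paths, quantile)
    retained = filter_paths(paths, threshold)
    path_pop = components(retained)
    record_pop = assign_records(cell_records, retained, path_pop)
    # records never snapped (not in any CellRecord) are unassigned too
    for rec in records:
        record_pop.setdefault(rec.record_id, UNASSIGNED)
    pops = classify(records, record_pop, robust_threshold, zero_fill)
    return PopulationPartition(
        retained_paths=retained,
        path_population=path_pop,
        record_population=record_pop,
        populations=pops,
    )
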