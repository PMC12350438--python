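"""Two-parameter sensitivity sweep over threshold and robust definition.

The accumulated-cost threshold (the species' assumed maximum yearly
dispersal capacity in cost-distance units) and the robust-population
definition (minimum median observations per year) are the two critical
parameters of the delineation.  The sweep evaluates the mean overall
expansion rate across robust populations for every combination on a grid,
re-using the single precomputed path set — path tracing does not depend on
either parameter, so only filtering, component labelling, assignment,
classification and regression re-run per grid point.

A well-behaved cost surface shows a plateau: a contiguous threshold range
over which the mean rate stays flat because no path cost falls inside it.
Operating points are chosen at the start of such an insensitive range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .delineation import UNASSIGNED, delineate
from .expansion import population_rates
from .lcp import LeastCostPath
from .observations import CellRecord, ObservationRecord

__all__ = ["default_grid", "sweep"]


def default_grid(paths: list[LeastCostPath], step: float = 0.01) -> np.ndarray:
    """Arithmetic threshold grid from 0 to the maximum path cost inclusive."""
    if step <= 0:
        raise ValueError("step must be positive")
    if not paths:
        raise ValueError("empty path set")
    max_cost = max(p.accumulated_cost for p in paths)
    n = int(np.floor(max_cost / step + 1e-9))
    grid = np.arange(n + 1) * step
    if grid[-1] < max_cost - 1e-12:
        grid = np.append(grid, max_cost)
    return grid


def sweep(
    paths: list[LeastCostPath],
    cell_records: list[CellRecord],
    records: list[ObservationRecord],
    thresholds: np.ndarray | list[float],
    robust_defs: list[int],
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Evaluate the pipeline at every (threshold, robust_def) grid point.

    Returns a long-format table with columns threshold, robust_def,
    n_populations, n_robust, n_unassigned, mean_rate_km_per_year (NaN when
    no robust population exists).  Rates are overall per-population fits;
    the mean across robust populations is unweighted.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("no thresholds supplied")
    rows = []
    for t in thresholds:
        part = delineate(
            paths, cell_records, records,
            threshold=float(t), robust_threshold=max(robust_defs),
            zero_fill=zero_fill,
        )
        pops = part.populations
        # per-population overall rates: computed once per threshold
        by_pop: dict[int, list[ObservationRecord]] = {}
        for rec in records:
            pid = part.record_population.get(rec.record_id, UNASSIGNED)
            if pid != UNASSIGNED:
                by_pop.setdefault(pid, []).append(rec)
        rates = population_rates(by_pop)
        rate_of = dict(zip(rates.population_id, rates.rate_km_per_year))
        for rdef in robust_defs:
            robust_ids = pops.index[pops.median_per_year >= rdef]
            robust_rates = [rate_of[p] for p in robust_ids if p in rate_of]
            rows.append(dict(
                threshold=float(t),
                robust_def=rdef,
                n_populations=len(pops),
                n_robust=len(robust_ids),
                n_unassigned=part.n_unassigned,
                mean_rate_km_per_year=(
                    float(np.mean(robust_rates)) if robust_rates else np.nan
                ),
            ))
    return pd.DataFrame(rows)
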