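"""Expansion-rate estimation by distance regression.

For each population the record with the earliest observation year serves
as the reference point p0.  Every record's planar Euclidean distance to p0
is computed, the per-year cumulative maximum of these distances tracks the
advancing invasion front, and an ordinary least squares regression of that
cumulative maximum (meters) against calendar year yields the expansion
rate as slope / 1000 in km/year.

Invasions commonly follow a sigmoidal trajectory — a lag phase of minimal
spread, a rapid expansion phase and a slow final phase.  Phase-wise fits
are supported through user-supplied breakpoint years (breakpoints are set
manually: one point per year leaves too few data for statistical
breakpoint detection); a breakpoint year belongs to both adjacent phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .observations import ObservationRecord

__all__ = [
    "ExpansionFit",
    "distances_to_first",
    "cummax_by_year",
    "fit_rate",
    "fit_phases",
    "population_rates",
]


@dataclass(frozen=True)
class ExpansionFit:
    """One regression fit: expansion rate in km/year with goodness of fit.

    ``r2`` is None (printed N/A) exactly when the response has zero
    variance — then the rate is 0 by definition.  ``phase`` is "overall"
    or a "from-until" label with both boundary years inclusive.
    """

    rate_km_per_year: float
    r2: float | None
    n_years: int
    phase: str = "overall"
    from_year: int | None = None
    until_year: int | None = None


def distances_to_first(
    records: list[ObservationRecord],
) -> tuple[dict[str, float], ObservationRecord]:
    """Planar Euclidean distance (meters) of every record to the first one.

    The reference p0 is the record with the earliest year; ties resolve to
    the first in input order.  Returns (record_id -> meters, p0).
    """
    if not records:
        raise ValueError("no records")
    p0 = min(records, key=lambda r: r.year)  # min is stable: first in input order
    out = {
        r.record_id: float(np.hypot(r.x - p0.x, r.y - p0.y)) for r in records
    }
    return out, p0


def cummax_by_year(
    distances: dict[str, float],
    years: dict[str, int],
    span: tuple[int, int],
) -> pd.Series:
    """Per-year cumulative maximum distance over a calendar-year span.

    For each year in [span[0], span[1]] the value is the maximum distance
    among records observed in or before that year; years without records
    carry the previous value forward.  The series is non-decreasing.
    """
    first, last = span
    obs_years = set(years.values())
    if obs_years and (min(obs_years) < first or max(obs_years) > last):
        raise ValueError("span does not cover all observation years")
    s = pd.Series(
        {rid: distances[rid] for rid in years}, dtype=float
    )
    yearly_max = s.groupby(pd.Series(years)).max()
    idx = pd.RangeIndex(first, last + 1, name="year")
    series = yearly_max.reindex(idx)
    return series.cummax().ffill()


def fit_rate(
    year_series: np.ndarray | pd.Index,
    cummax_series: np.ndarray | pd.Series,
    phase: str = "overall",
) -> ExpansionFit:
    """OLS fit of the cumulative maximum distance (meters) against year.

    The slope divided by 1000 is the expansion rate in km/year; r2 is the
    coefficient of determination.  A zero-variance response yields rate 0
    with r2 = None.  Needs at least 2 years.
    """
    years = np.asarray(year_series, dtype=float)
    y = np.asarray(cummax_series, dtype=float)
    if years.size < 2:
        raise ValueError("regression needs at least 2 years")
    if np.any(np.diff(y) < 0):
        raise ValueError("cumulative maximum series must be non-decreasing")
    from_year, until_year = int(years.min()), int(years.max())
    if np.ptp(y) == 0:
        return ExpansionFit(0.0, None, years.size, phase, from_year, until_year)
    model = sm.OLS(y, sm.add_constant(years)).fit()
    rate = float(model.params[1]) / 1000.0
    # OLS slope of a non-decreasing response on increasing years is >= 0
    assert rate >= -1e-12, f"negative expansion rate {rate} from monotone response"
    return ExpansionFit(
        max(rate, 0.0), float(model.rsquared), years.size, phase,
        from_year, until_year,
    )


def fit_phases(
    year_series: np.ndarray | pd.Index,
    cummax_series: np.ndarray | pd.Series,
    breakpoints: list[int],
) -> list[ExpansionFit]:
    """Independent OLS fits per phase delimited by breakpoint years.

    Phases are [first, b1], [b1, b2], ..., [bk, last]; each breakpoint
    year belongs to both adjacent phases.  With no breakpoints this equals
    a single :func:`fit_rate`.  Raises if any phase has fewer than 2 years.
    """
    years = np.asarray(year_series, dtype=int)
    y = np.asarray(cummax_series, dtype=float)
    if sorted(breakpoints) != list(breakpoints) or len(set(breakpoints)) != len(breakpoints):
        raise ValueError("breakpoints must be strictly increasing")
    first, last = int(years.min()), int(years.max())
    for b in breakpoints:
        if not first < b < last:
            raise ValueError(f"breakpoint {b} outside the span ({first}, {last})")
    bounds = [first, *breakpoints, last]
    fits = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (years >= lo) & (years <= hi)
        if sel.sum() < 2:
            raise ValueError(f"phase {lo}-{hi} has fewer than 2 years")
        fits.append(fit_rate(years[sel], y[sel], phase=f"{lo}-{hi}"))
    return fits


def population_rates(
    records_by_pop: dict[int, list[ObservationRecord]],
    breakpoints: dict[int, list[int]] | None = None,
) -> pd.DataFrame:
    """Overall (and optional phase-wise) expansion fits for each population.

    ``breakpoints`` maps population id to its manually chosen breakpoint
    years.  Populations with a single observation year are skipped (no
    regression possible).  Returns a long-format table with one row per
    fit (population_id, phase, from/until year, rate, r2, n_years).
    """
    rows = []
    for pid, members in sorted(records_by_pop.items()):
        dists, p0 = distances_to_first(members)
        yrs = {m.record_id: m.year for m in members}
        span = (min(yrs.values()), max(yrs.values()))
        if span[0] == span[1]:
            continue
        series = cummax_by_year(dists, yrs, span)
        fits = [fit_rate(series.index, series)]
        bp = (breakpoints or {}).get(pid)
        if bp:
            fits.extend(fit_phases(series.index, series, bp))
        for f in fits:
            rows.append(dict(
                population_id=pid, phase=f.phase, from_year=f.from_year,
                until_year=f.until_year, rate_km_per_year=f.rate_km_per_year,
                r2=f.r2, n_years=f.n_years,
                p0_id=p0.record_id, p0_year=p0.year,
            ))
    return pd.DataFrame(
        rows,
        columns=["population_id", "phase", "from_year", "until_year",
                 "rate_km_per_year", "r2", "n_years", "p0_id", "p0_year"],
    )
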