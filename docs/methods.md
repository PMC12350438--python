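# Methods

## Model

The package treats invasion spread as a spatio-temporal linking problem
on a raster landscape.  Assumptions:

- **Cost as dispersal impedance.**  Habitat suitability is taken as a
  proxy for dispersal permeability: cost is the linear inversion of
  suitability rescaled to [0, 1].  This is an assumption, not a fitted
  relation; users with an independently estimated resistance surface can
  bypass the inversion (`mode="cost"`, unbounded values allowed).
- **Annual time steps.**  One generation per year (univoltine species):
  each record observed in year *t* descends, in the model, from the
  population state strictly before *t*.  By default records of the same
  year never connect to each other (strictly-earlier linking), which
  makes the result independent of record ordering within a year; the
  alternative reading — each traced record immediately becomes a source
  for the rest of its cohort — is available as `chain_within_year=True`.
- **Least-cost linking.**  Every new cell is linked to the *nearest*
  previously known cell by cost distance, i.e. a multi-source shortest
  path.  Paths are deterministic optima, an optimistic view of
  connectivity; no stochastic path ensembles or circuit-theory current
  maps are computed.
- **Delineation by thresholding.**  The accumulated-cost threshold plays
  the role of a maximum yearly dispersal capacity.  Removing
  above-threshold paths and taking connectivity components both separates
  independent introductions and splits off jump-dispersal subpopulations;
  the method cannot distinguish the two causes.

## Grid graph and numerics

- 8-connected neighbourhood with geometric edge weights
  `L · (c_a + c_b)/2`, `L ∈ {1, √2}`, in **cell units** (not meters), so
  accumulated costs are dimensionless and comparable across rasters of
  different resolution.  A 16-way ("knight's move") neighbourhood is not
  implemented.
- The multi-source Dijkstra accumulation is implemented in-package with a
  binary heap.  When several optimal predecessors exist, the traceback
  keeps the one with the smallest (row, col) lexicographic index —
  accumulated costs are unaffected, but path geometries become
  reproducible.  Equality of floating-point path costs is tested exactly;
  genuinely tied optima arise from symmetric geometries where the
  alternatives are exact duplicates in cost.
- Costs of exactly 0 are legal (zero-cost corridors); a path can then
  have accumulated cost 0 over a nonzero distance.  NoData cells are +∞
  and absolute barriers.
- Cells are half-open: a point on a shared cell edge belongs to the cell
  to its right/below in index space.  Rows increase downward, columns
  rightward, 0-based, throughout.
- Suitability inversion requires a non-degenerate value range and, when
  bounds are user-supplied, rejects out-of-range values instead of
  clamping.

## Delineation conventions

- Path removal is strict: a path at exactly the threshold is retained.
- The threshold ↔ quantile correspondence uses the empirical CDF with no
  interpolation; `threshold_of_quantile` always returns an observed path
  cost.
- Population ids are assigned deterministically (earliest member path
  year, then smallest endpoint index); names are
  `"<label> <first_year>"` from an optional country/label attribute, with
  `a/b/c` suffixes on collisions ordered by descending record count.
- **Median observations per year** uses raw (pre-dedup) record counts
  over every calendar year from the population's first to latest
  observation, zero-filling silent years — silent years are evidence of
  poor coverage and should lower the median.  `zero_fill=False` gives the
  occupied-years-only alternative.  A median exactly at the robust
  threshold counts as robust.
- Records snapped to impassable cells are kept but flagged; they can
  never be path endpoints and end unassigned, surfacing data problems
  instead of hiding them.

## Expansion rates

- Distances feed on raw records (not deduped cells): the reference p0 is
  the earliest record, ties broken by input order (the choice shifts all
  distances, so it is exposed in the output table).
- The regression series has one point per calendar year over
  [first, latest] with carry-forward for silent years; omitting silent
  years would re-weight the fit toward well-sampled periods.
- A zero-variance response (front never advances) yields rate 0 with R²
  reported as N/A rather than a degenerate fit.
- Phase fits share their breakpoint years with both adjacent phases, so a
  phase needs at least two calendar years.  Breakpoints are always
  user-supplied; no automatic changepoint detection is attempted.
- The OLS slope of a non-decreasing response on increasing years is
  provably non-negative; the implementation asserts this on every fit.

## Sensitivity sweep

Paths are computed once; only filtering, component labelling, assignment,
classification and regression re-run per grid point, which keeps a
~7,000 × 11 grid tractable.  The mean across robust populations is
unweighted, and overall (not phase-wise) rates are used.  The default
threshold grid runs from 0 to the maximum path cost in steps of 0.01.

## Synthetic scenarios

The generator expresses ground truth in the pipeline's own metric: every
annual cohort is sampled uniformly from the cells within a cost-distance
budget *b* of the introduction's previous records, computed with the same
accumulation routine the path engine uses.  Consequently every traced
path of a single-introduction cluster costs at most *b*, and delineation
with any threshold in [*b*, barrier-crossing cost) recovers the true
introductions — this is what makes plateau behaviour constructible.

Preset scenarios (grid cells are 10 km, mirroring a coarse continental
suitability map; yearly cohorts of ~12 records per introduction, uneven
in the plateau preset, emulate modest citizen-science effort):

- **one-population** — single introduction, uniform cost 0.2, budget 1.0,
  8 years.
- **two-basin** — two introductions either side of an impassable (NoData)
  strip; the later introduction's seed record is provably isolated and
  its descendants form a second population.
- **plateau** — two distant introductions staggered by three years on a
  uniform surface; the later seed is traced back as a single jump path an
  order of magnitude costlier than any within-cluster path, creating a
  wide insensitive threshold range.

What the simulator does **not** emulate: spatially biased reporting,
coordinate error, multi-modal dispersal kernels, temporally varying
landscapes.  Passing tests therefore demonstrate algorithmic correctness
and parameter-sensitivity behaviour, not robustness to real-world
observation artefacts.

## Problem sizes and validation

The test suite and the acceptance script run on synthetic problems sized
for exactness checks rather than realism: random rasters up to 7×7 are
compared against a brute-force Dijkstra on the explicit graph (tolerance
1e-9, with an additional cross-check against scikit-image's geometric
MCP implementation), uniform 50×50 grids against the octile closed form
`max(|Δr|,|Δc|) + (√2−1)·min(|Δr|,|Δc|)`, and the end-to-end scenarios
use 40×60 to 40×120 grids with 150–250 records over 8–9 years, 10–20
simulation seeds per property.

## Known limitations

- No reprojection or resampling: all inputs must share one projected,
  equal-distance CRS; the raster format is plain-text ASCII grid with
  square cells.
- Path geometries (not costs) may differ from other least-cost tools
  whose predecessor tie-breaking is unspecified.
- The delineation inherits the resolution of the cost surface: barriers
  narrower than a cell vanish, and coarse grids can let paths cross
  fine-scale barriers.
- Expansion rates from sparse populations are unreliable; that is what
  the robust/sparse classification is for, and sparse populations should
  not be interpreted.
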