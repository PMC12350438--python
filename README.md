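# seqlcp — sequential least-cost modelling of invasive-species spread

`seqlcp` infers the population structure of an invading species from
occurrence records alone — no genetic data required — and estimates each
population's range-expansion rate.  It is aimed at spatial ecologists and
invasion biologists working with opportunistic occurrence data (citizen
science, literature records) and a habitat-suitability or resistance map
of the invaded region.

## The method

The landscape is a **cost surface**: a raster in a projected,
equal-distance CRS whose cell values quantify how strongly movement
through that cell is impeded.  A suitability map *S* is converted to cost
by inversion and rescaling, `cost = (S_max − S) / (S_max − S_min)`, so
cost ∈ [0, 1] and NoData cells (ocean) are impassable (+∞).

**Sequential least-cost modelling.**  Occurrence records are snapped to
raster cells and deduplicated (one record per cell, earliest year).  In
annual time steps — matching a univoltine life cycle — every cell newly
occupied in year *t* is linked to the nearest cell known before *t* by a
least-cost path on the 8-connected grid graph, where a move between
adjacent cells costs `L · (c_a + c_b)/2` with `L = 1` (orthogonal) or
`√2` (diagonal) in cell units.  The union of paths over all years is the
dispersal network, kept unfiltered.

**Population delineation.**  Paths whose accumulated cost exceeds a
threshold *T* — the assumed maximum yearly dispersal capacity in
cost-distance units — are removed; connected components of the remaining
paths (two paths connect iff they share an endpoint cell) define
populations; records are assigned through path-endpoint cells, and
records isolated by barriers or path removal stay unassigned.  Each
population's data coverage is the median raw-record count per calendar
year (silent years count as zero); populations with median ≥ *m* (default
10) are **robust**, the rest sparse.

**Expansion rates.**  Within each population, with *p₀* the earliest
record, the yearly cumulative maximum Euclidean distance ‖pᵢ − p₀‖ is
regressed on year by OLS; the slope / 1000 is the expansion rate in
km/year.  Piecewise fits over manually chosen breakpoint years separate
lag, expansion and final phases of a sigmoidal invasion.

**Sensitivity.**  Both critical parameters (*T*, *m*) are swept on a
grid, re-using the fixed path network; an operating *T* is chosen at the
start of an insensitive plateau of the mean robust-population rate.

A synthetic invasion simulator with ground truth (known introduction
labels, annual cost-distance budgets, barrier geometry) validates every
stage.

## Worked example

Simulate two introductions separated by an impassable barrier strip, then
run the full pipeline (`python examples/03_delineate_and_rates.py`):

```
populations (median = raw records per calendar year, zero-filled):
                 name  first_year  latest_year  n_records  median_per_year  status
population_id
1              A 2008        2008         2016         97             12.0  robust
2              B 2010        2010         2016         73             12.0  robust

unassigned records: 0

expansion rates (overall fits):
 population_id   phase  rate_km_per_year       r2  n_years
             1 overall         26.939010 0.917662        9
             2 overall         26.911582 0.956743        7
```

Both simulated introductions are recovered as distinct robust populations
(the barrier makes any cross-path impossible), and each rate is that
population's front advance in km/year with the R² of its distance
regression.  `examples/04_sensitivity_sweep.py` shows the threshold
plateau: the mean rate is flat for any threshold between the largest
within-cluster path cost and the single expensive jump path, then jumps
when the two populations merge into an implausible super-population.
The same analyses run from the shell:

```
seqlcp simulate --scenario two-basin --seed 1 --out-dir sim/
seqlcp all --cost sim/cost.asc --obs sim/obs.csv --mode cost \
           --threshold 1.0 --out-dir run/
```

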