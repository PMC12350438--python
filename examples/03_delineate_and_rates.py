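"""Delineate populations and estimate their expansion rates.

High-cost paths are removed at an accumulated-cost threshold, connected
paths form populations, records are assigned through shared endpoint
cells, and each population's expansion rate is the OLS slope of the
yearly cumulative maximum distance from its first observation (km/year).
"""

from seqlcp import (
    UNASSIGNED,
    dedupe,
    delineate,
    generate,
    population_rates,
    run_sequential,
    snap,
    two_basin_scenario,
)

cost, records, truth = generate(two_basin_scenario(seed=0))
cells = dedupe(records, snap(records, cost), cost)
result = run_sequential(cost, cells)

part = delineate(result.paths, cells, records, threshold=1.0,
                 robust_threshold=10)
print("populations (median = raw records per calendar year, zero-filled):")
print(part.populations.to_string())
print(f"\nunassigned records: {part.n_unassigned}")

by_pop = {}
for rec in records:
    pid = part.record_population[rec.record_id]
    if pid != UNASSIGNED:
        by_pop.setdefault(pid, []).append(rec)
rates = population_rates(by_pop)
print("\nexpansion rates (overall fits):")
print(rates[["population_id", "phase", "rate_km_per_year", "r2", "n_years"]]
      .to_string(index=False))
print(
    "\nBoth introductions are recovered as robust populations; the rates"
    "\nreflect each simulated front's advance in km/year with its R^2."
)
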