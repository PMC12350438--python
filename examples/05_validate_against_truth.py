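"""Validate the whole pipeline against simulator ground truth.

The synthetic generator spreads each introduction with a known annual
cost-distance budget, so the true population labels and realized front
speeds are known exactly.  The recovery report scores the delineation
(adjusted Rand agreement) and the rate estimates (absolute error vs the
realized speed measured from the truth records).
"""

from seqlcp import (
    UNASSIGNED,
    dedupe,
    delineate,
    generate,
    population_rates,
    recovery_report,
    run_sequential,
    snap,
    two_basin_scenario,
)

cost, records, truth = generate(two_basin_scenario(seed=42))
cells = dedupe(records, snap(records, cost), cost)
result = run_sequential(cost, cells)
part = delineate(result.paths, cells, records, threshold=1.0,
                 robust_threshold=10)

by_pop = {}
for rec in records:
    pid = part.record_population[rec.record_id]
    if pid != UNASSIGNED:
        by_pop.setdefault(pid, []).append(rec)
rates = population_rates(by_pop)

report = recovery_report(records, truth, part, rates)
print(f"true introductions:   {report['n_true_introductions']}")
print(f"delineated:           {report['n_populations']} populations, "
      f"{report['n_unassigned']} unassigned records")
print(f"label agreement:      {report['label_agreement']:.3f} (adjusted Rand; 1 = perfect)")
print("realized front speed and fitted-rate error (km/year):")
for label, speed in report["realized_speed_km_per_year"].items():
    err = report["rate_abs_error_km_per_year"].get(label)
    print(f"  introduction {label}: speed {speed:.2f}, |error| {err:.3f}")
print(
    "\nAgreement 1.0 means every record was grouped with its true"
    "\nintroduction; the rate errors are zero because the fitted fronts"
    "\ncoincide with the truth-derived fronts for a perfect partition."
)
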