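"""Sweep the two critical parameters and find the insensitive plateau.

The accumulated-cost threshold and the robust-population definition are
varied on a grid; for each combination the mean overall expansion rate
across robust populations is recorded.  On the plateau scenario the
staggered second introduction creates one expensive jump path, so the
mean rate is flat for any threshold between the within-cluster maximum
and the jump cost — the signature used to choose an operating point.
"""

import numpy as np

from seqlcp import (
    dedupe,
    generate,
    plateau_scenario,
    run_sequential,
    snap,
    sweep,
)

cost, records, truth = generate(plateau_scenario(seed=0))
cells = dedupe(records, snap(records, cost), cost)
result = run_sequential(cost, cells)

costs = sorted(p.accumulated_cost for p in result.paths)
print(f"paths: {len(result.paths)}; largest within-cluster cost "
      f"{costs[-2]:.3f}; jump-path cost {costs[-1]:.3f}")

grid = np.round(np.linspace(0.2, costs[-1] + 0.2, 12), 3)
table = sweep(result.paths, cells, records, grid, robust_defs=[5, 10, 15])
pivot = table.pivot(index="threshold", columns="robust_def",
                    values="mean_rate_km_per_year")
pivot["n_pops"] = table[table.robust_def == 10].set_index("threshold").n_populations
print("\nmean expansion rate across robust populations (km/year):")
print(pivot.round(2).to_string())
print(
    "\nBetween the two cost levels the curve is flat (the insensitive"
    "\nrange) and two populations persist; past the jump cost they merge"
    "\ninto one and the mean rate shifts — mirroring how an operating"
    "\nthreshold is chosen at the start of a plateau."
)
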