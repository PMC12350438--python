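"""Independent reference implementations used only to check seqlcp.

The cost-distance oracle builds the explicit 8-neighbour graph with
geometric edge weights L * (cost_a + cost_b) / 2 and runs networkx's
Dijkstra — a completely separate code path from the package's own grid
accumulation.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

SQRT2 = math.sqrt(2.0)


def brute_force_cost_distance(values: np.ndarray, sources: list[tuple[int, int]]) -> np.ndarray:
    """Multi-source cost distance on the explicit 8-neighbour graph."""
    nrows, ncols = values.shape
    graph = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            if not np.isfinite(values[r, c]):
                continue
            graph.add_node((r, c))
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < nrows and 0 <= nc < ncols and np.isfinite(values[nr, nc]):
                    length = SQRT2 if dr and dc else 1.0
                    w = length * (values[r, c] + values[nr, nc]) / 2.0
                    graph.add_edge((r, c), (nr, nc), weight=w)
    passable_sources = [s for s in sources if np.isfinite(values[s])]
    dist = np.full((nrows, ncols), np.inf)
    lengths = nx.multi_source_dijkstra_path_length(graph, passable_sources)
    for (r, c), d in lengths.items():
        dist[r, c] = d
    return dist


def octile(dr: int, dc: int) -> float:
    """Closed-form 8-connected grid distance in cell units."""
    a, b = abs(dr), abs(dc)
    return max(a, b) + (SQRT2 - 1.0) * min(a, b)
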