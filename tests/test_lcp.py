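import math

import numpy as np
import pytest

from seqlcp import (
    CellRecord,
    CostRaster,
    GridTransform,
    accumulate,
    run_sequential,
    step_cost,
    trace_year,
)
from seqlcp.lcp import trace_path

from conftest import random_cost_raster
from oracles import brute_force_cost_distance, octile

SQRT2 = math.sqrt(2.0)


class TestStepCost:
    @pytest.mark.parametrize(
        "a, b, move, expected",
        [
            (1.0, 1.0, "orthogonal", 1.0),
            (1.0, 1.0, "diagonal", SQRT2),
            (0.2, 0.6, "orthogonal", 0.4),
            (0.2, 0.6, "diagonal", 0.4 * SQRT2),
        ],
    )
    def test_mean_of_endpoints_times_length(self, a, b, move, expected):
        assert step_cost(a, b, move) == pytest.approx(expected, abs=1e-12)

    def test_impassable_endpoint_is_infinite(self):
        assert math.isinf(step_cost(np.inf, 1.0, "orthogonal"))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            step_cost(-0.1, 1.0, "orthogonal")


class TestAccumulate:
    def test_uniform_grid_closed_form(self, uniform_cost):
        dist, _ = accumulate(uniform_cost, [(0, 0)])
        assert dist[0, 3] == pytest.approx(3.0, abs=1e-12)
        assert dist[2, 2] == pytest.approx(2 * SQRT2, abs=1e-12)
        assert dist[1, 2] == pytest.approx(1 + SQRT2, abs=1e-12)

    def test_source_cells_zero(self, uniform_cost):
        dist, _ = accumulate(uniform_cost, [(3, 4), (7, 1)])
        assert dist[3, 4] == 0.0 and dist[7, 1] == 0.0

    def test_octile_closed_form_full_grid(self):
        t = GridTransform(0, 500_000.0, 10_000.0, 10_000.0)
        c = 0.7
        cost = CostRaster(values=np.full((50, 50), c), transform=t)
        src = (17, 31)
        dist, _ = accumulate(cost, [src])
        for r in range(50):
            for col in range(50):
                expected = c * octile(r - src[0], col - src[1])
                assert dist[r, col] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_dijkstra(self, seed):
        rng = np.random.default_rng(1000 + seed)
        cost = random_cost_raster(rng, 6, 6)
        passable = np.argwhere(np.isfinite(cost.values))
        if len(passable) == 0:
            pytest.skip("fully impassable draw")
        n_src = int(rng.integers(1, 4))
        sources = [tuple(passable[i]) for i in
                   rng.choice(len(passable), size=min(n_src, len(passable)),
                              replace=False)]
        dist, _ = accumulate(cost, sources)
        oracle = brute_force_cost_distance(cost.values, sources)
        np.testing.assert_allclose(dist, oracle, atol=1e-9)

    def test_matches_skimage_mcp_geometric(self):
        # cross-check against scikit-image's geometric MCP implementation
        graph = pytest.importorskip("skimage.graph")
        rng = np.random.default_rng(42)
        cost = random_cost_raster(rng, 12, 15, p_nodata=0.1)
        passable = np.argwhere(np.isfinite(cost.values))
        sources = [tuple(passable[i]) for i in (0, len(passable) // 2)]
        dist, _ = accumulate(cost, sources)
        mcp = graph.MCP_Geometric(cost.values)
        sk_dist, _ = mcp.find_costs(sources)
        np.testing.assert_allclose(dist, sk_dist, atol=1e-9)

    def test_traceback_self_consistent(self):
        # re-costing the traced geometry reproduces the accumulated cost
        rng = np.random.default_rng(5)
        cost = random_cost_raster(rng, 8, 8, p_nodata=0.1)
        passable = np.argwhere(np.isfinite(cost.values))
        src = tuple(passable[0])
        dist, pred = accumulate(cost, [src])
        for cell in map(tuple, passable):
            if not np.isfinite(dist[cell]):
                continue
            cells = trace_path(pred, cell)
            assert cells[0] == src or dist[cells[0]] == 0.0
            assert cells[-1] == cell
            total = 0.0
            for (r1, c1), (r2, c2) in zip(cells, cells[1:]):
                assert max(abs(r1 - r2), abs(c1 - c2)) == 1  # 8-neighbours
                move = "diagonal" if (r1 != r2 and c1 != c2) else "orthogonal"
                total += step_cost(cost.values[r1, c1], cost.values[r2, c2], move)
            assert total == pytest.approx(dist[cell], abs=1e-9)

    def test_all_sources_impassable_rejected(self, transform):
        vals = np.ones((3, 3))
        vals[0, 0] = np.inf
        cost = CostRaster(values=vals, transform=transform)
        with pytest.raises(ValueError, match="passable"):
            accumulate(cost, [(0, 0)])

    def test_zero_cost_corridor(self, transform):
        vals = np.ones((3, 5))
        vals[1, :] = 0.0
        cost = CostRaster(values=vals, transform=transform)
        dist, _ = accumulate(cost, [(1, 0)])
        assert dist[1, 4] == 0.0  # zero cost over nonzero distance is legal


class TestTraceYear:
    def test_single_pair(self, uniform_cost):
        known = [CellRecord(0, 0, 2010, ["a"])]
        new = [CellRecord(0, 3, 2011, ["b"])]
        paths, isolated = trace_year(uniform_cost, known, new, 2011)
        assert not isolated and len(paths) == 1
        assert paths[0].source == (0, 0) and paths[0].target == (0, 3)
        assert paths[0].accumulated_cost == pytest.approx(3.0)

    def test_island_record_reported_isolated(self, transform):
        vals = np.ones((5, 5))
        vals[1:4, 1:4] = np.inf
        vals[2, 2] = 1.0  # island surrounded by barrier
        cost = CostRaster(values=vals, transform=transform)
        known = [CellRecord(0, 0, 2010, ["a"])]
        new = [CellRecord(2, 2, 2011, ["b"])]
        paths, isolated = trace_year(cost, known, new, 2011)
        assert paths == [] and [i.cell for i in isolated] == [(2, 2)]

    def test_nearest_of_two_sources_wins(self, uniform_cost):
        known = [CellRecord(0, 0, 2009, ["a"]), CellRecord(9, 9, 2010, ["b"])]
        new = [CellRecord(7, 7, 2011, ["c"])]
        paths, _ = trace_year(uniform_cost, known, new, 2011)
        assert paths[0].source == (9, 9)  # octile-closer source
        assert paths[0].accumulated_cost == pytest.approx(2 * SQRT2)

    def test_year_preconditions(self, uniform_cost):
        with pytest.raises(ValueError):
            trace_year(uniform_cost, [CellRecord(0, 0, 2011, ["a"])],
                       [CellRecord(1, 1, 2011, ["b"])], 2011)


class TestRunSequential:
    def test_seed_year_only_gives_no_paths(self, uniform_cost):
        cells = [CellRecord(0, 0, 2010, ["a"]), CellRecord(5, 5, 2010, ["b"])]
        res = run_sequential(uniform_cost, cells)
        assert res.paths == [] and len(res.seeds) == 2

    def test_collinear_annual_chain(self, uniform_cost):
        cells = [CellRecord(0, i, 2008 + i, [str(i)]) for i in range(5)]
        res = run_sequential(uniform_cost, cells)
        assert len(res.paths) == 4
        for p in res.paths:
            assert p.accumulated_cost == pytest.approx(1.0)
            assert p.source[1] == p.target[1] - 1  # links the previous cell

    def test_path_count_identity(self, uniform_cost):
        rng = np.random.default_rng(11)
        cells = [CellRecord(int(r), int(c), int(y), [f"{r}-{c}"])
                 for (r, c), y in
                 {(tuple(rng.integers(0, 10, 2))): rng.integers(2008, 2015)
                  for _ in range(30)}.items()]
        res = run_sequential(uniform_cost, cells)
        assert len(res.paths) == len(cells) - len(res.seeds) - len(res.isolated)

    def test_order_invariance_within_year(self, uniform_cost):
        cells = [CellRecord(0, 0, 2008, ["s"]),
                 CellRecord(3, 3, 2009, ["a"]), CellRecord(6, 1, 2009, ["b"])]
        res_fwd = run_sequential(uniform_cost, cells)
        res_rev = run_sequential(uniform_cost, list(reversed(cells)))
        key = lambda p: (p.target, p.source, p.accumulated_cost)
        assert sorted(map(key, res_fwd.paths)) == sorted(map(key, res_rev.paths))

    def test_within_year_records_not_chained_by_default(self, uniform_cost):
        # two same-year records both trace to the seed, not to each other
        cells = [CellRecord(0, 0, 2008, ["s"]),
                 CellRecord(0, 2, 2009, ["a"]), CellRecord(0, 4, 2009, ["b"])]
        res = run_sequential(uniform_cost, cells)
        assert all(p.source == (0, 0) for p in res.paths)
        chained = run_sequential(uniform_cost, cells, chain_within_year=True)
        assert sorted(p.source for p in chained.paths) == [(0, 0), (0, 2)]

    def test_deterministic_geometry_tie_break(self, uniform_cost):
        cells = [CellRecord(0, 0, 2008, ["s"]), CellRecord(4, 4, 2009, ["t"])]
        g1 = run_sequential(uniform_cost, cells).paths[0].cells
        g2 = run_sequential(uniform_cost, cells).paths[0].cells
        assert g1 == g2
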