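import numpy as np
import pytest

from seqlcp import (
    UNASSIGNED,
    CellRecord,
    LeastCostPath,
    ObservationRecord,
    components,
    delineate,
    filter_paths,
    quantile_of_threshold,
    threshold_of_quantile,
)
from seqlcp.delineation import assign_records, classify


def path(source, target, cost, year=2010):
    return LeastCostPath(source=source, target=target, year=year,
                         accumulated_cost=cost, cells=(source, target))


class TestThresholdQuantile:
    def test_empirical_cdf(self):
        paths = [path((0, 0), (0, i), c) for i, c in enumerate([1, 2, 3, 4], 1)]
        assert quantile_of_threshold(paths, 2.0) == 0.5

    def test_q1_gives_maximum(self):
        paths = [path((0, 0), (0, i), c) for i, c in enumerate([0.5, 9.0, 3.3], 1)]
        assert threshold_of_quantile(paths, 1.0) == 9.0

    def test_pairing_mirrors_ecdf(self):
        # threshold_of_quantile inverts quantile_of_threshold on observed costs
        rng = np.random.default_rng(2)
        paths = [path((0, 0), (0, i), float(c))
                 for i, c in enumerate(rng.uniform(0, 68, size=200), 1)]
        for q in (0.5, 0.75, 0.947):
            t = threshold_of_quantile(paths, q)
            assert quantile_of_threshold(paths, t) >= q
        assert quantile_of_threshold(paths, threshold_of_quantile(paths, 0.947)) \
            == pytest.approx(0.95, abs=0.005)

    def test_empty_paths_error(self):
        with pytest.raises(ValueError):
            quantile_of_threshold([], 1.0)


class TestFilterPaths:
    def test_exactly_at_threshold_retained(self):
        paths = [path((0, 0), (1, 1), c) for c in (1.0, 4.4, 4.41)]
        kept = filter_paths(paths, 4.4)
        assert [p.accumulated_cost for p in kept] == [1.0, 4.4]

    def test_threshold_above_max_keeps_all(self):
        paths = [path((0, 0), (1, 1), c) for c in (1.0, 2.0)]
        assert len(filter_paths(paths, 99.0)) == 2

    def test_zero_threshold_on_positive_costs_keeps_none(self):
        paths = [path((0, 0), (1, 1), c) for c in (0.1, 2.0)]
        assert filter_paths(paths, 0.0) == []


class TestComponents:
    def test_shared_endpoint_merges(self):
        a, b, c, d, e = (0, 0), (0, 1), (0, 2), (5, 5), (5, 6)
        paths = [path(a, b, 1, 2009), path(b, c, 1, 2010), path(d, e, 1, 2011)]
        pops = components(paths)
        assert pops[0] == pops[1] != pops[2]

    def test_empty_paths_no_populations(self):
        assert components([]) == {}

    def test_ids_ordered_by_earliest_year(self):
        late = path((9, 9), (9, 8), 1, year=2015)
        early = path((0, 0), (0, 1), 1, year=2009)
        pops = components([late, early])
        assert pops[1] == 1 and pops[0] == 2  # early component gets id 1

    def test_partition_refinement_under_threshold_increase(self):
        rng = np.random.default_rng(8)
        cells = [(int(r), int(c)) for r, c in rng.integers(0, 30, size=(40, 2))]
        paths = [path(cells[int(i)], cells[int(j)], float(w), 2009 + int(i) % 5)
                 for i, j, w in zip(rng.integers(0, 40, 60),
                                    rng.integers(0, 40, 60),
                                    rng.uniform(0, 10, 60))]
        for t1, t2 in [(1.0, 3.0), (2.5, 2.5), (4.0, 9.0)]:
            p1 = components(filter_paths(paths, t1))
            p2 = components(filter_paths(paths, t2))
            r1 = {id(p): pop for p, pop in zip(filter_paths(paths, t1), p1.values())}
            # every T1 population maps into exactly one T2 population
            mapping = {}
            kept2 = filter_paths(paths, t2)
            idx2 = {id(p): p2[i] for i, p in enumerate(kept2)}
            for p, pop1 in r1.items():
                pop2 = idx2[p]
                assert mapping.setdefault(pop1, pop2) == pop2


class TestAssignClassify:
    def test_record_in_endpoint_cell_assigned(self):
        p = path((2, 2), (3, 3), 1.0)
        cells = [CellRecord(2, 2, 2009, ["r1", "r2"]), CellRecord(8, 8, 2010, ["r3"])]
        assign = assign_records(cells, [p], {0: 1})
        assert assign == {"r1": 1, "r2": 1, "r3": UNASSIGNED}

    def test_removed_path_leaves_record_unassigned(self):
        p = path((2, 2), (3, 3), 9.0)
        cells = [CellRecord(3, 3, 2010, ["r"])]
        retained = filter_paths([p], 4.4)
        assign = assign_records(cells, retained, components(retained))
        assert assign["r"] == UNASSIGNED

    @pytest.mark.parametrize(
        "median, expected", [(37.0, "robust"), (10.0, "robust"), (1.0, "sparse")]
    )
    def test_robust_boundary(self, median, expected):
        # constant yearly counts make the median explicit
        records = [
            ObservationRecord(f"{y}-{i}", 0, 0, y)
            for y in (2019, 2020) for i in range(int(median))
        ]
        assign = {r.record_id: 1 for r in records}
        table = classify(records, assign, robust_threshold=10)
        assert table.iloc[0].status == expected

    def test_zero_filled_years_lower_the_median(self):
        # counts {2019: 3, 2021: 5} -> series [3, 0, 5], median 3
        records = [ObservationRecord(f"a{i}", 0, 0, 2019) for i in range(3)]
        records += [ObservationRecord(f"b{i}", 0, 0, 2021) for i in range(5)]
        assign = {r.record_id: 1 for r in records}
        table = classify(records, assign, robust_threshold=10)
        assert table.iloc[0].median_per_year == 3.0
        assert table.iloc[0].status == "sparse"
        occupied_only = classify(records, assign, robust_threshold=4, zero_fill=False)
        assert occupied_only.iloc[0].median_per_year == 4.0

    def test_name_suffixes_on_collision(self):
        records = (
            [ObservationRecord(f"a{i}", 0, 0, 2009 + (i % 3), label="Italy")
             for i in range(20)]
            + [ObservationRecord(f"b{i}", 0, 0, 2009 + (i % 2), label="Italy")
               for i in range(4)]
        )
        assign = {r.record_id: (1 if r.record_id.startswith("a") else 2)
                  for r in records}
        table = classify(records, assign, robust_threshold=10)
        assert set(table.name) == {"Italy 2009a", "Italy 2009b"}
        # larger population takes suffix 'a'
        assert table.loc[table.n_records.idxmax(), "name"] == "Italy 2009a"


class TestDelineateCounting:
    def test_record_conservation(self):
        # population counts + unassigned = raw total
        paths = [path((0, 0), (0, 1), 1.0, 2009), path((5, 5), (5, 6), 8.0, 2010)]
        cells = [
            CellRecord(0, 0, 2008, ["a", "b"]), CellRecord(0, 1, 2009, ["c"]),
            CellRecord(5, 5, 2009, ["d"]), CellRecord(5, 6, 2010, ["e"]),
        ]
        records = [ObservationRecord(i, 0, 0, 2009) for i in "abcde"]
        part = delineate(paths, cells, records, threshold=4.4, robust_threshold=10)
        n_in_pops = int(part.populations.n_records.sum())
        assert n_in_pops + part.n_unassigned == len(records)
        assert part.n_unassigned == 2  # 'd', 'e' lost their only path

    def test_threshold_quantile_exclusive(self):
        with pytest.raises(ValueError):
            delineate([], [], [], threshold=1.0, quantile=0.9)
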