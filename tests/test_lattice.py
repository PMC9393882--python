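"""Lattice construction, canonical lag ordering, point assignment, geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lagcross import (
    GridCell,
    Lattice,
    assign_lag_grids,
    assign_point_to_grid,
    canonical_order,
    classify_precede_follow,
    count_design_combinations,
    hosa_geometry,
    read_lattice,
    write_lattice,
)
from lagcross.lattice import (
    CONDITIONS,
    LatticeError,
    canonical_lag_label,
    lag_span,
    precede_follow_percentages,
)


class TestBaltimoreFixture:
    def test_cell_and_monitor_counts(self, baltimore):
        assert len(baltimore) == 99
        assert len(baltimore.monitor_cells) == 15
        assert baltimore.total_monitors == 17

    def test_triple_monitor_cell(self, baltimore):
        assert baltimore.cell(6, 6).n_monitors == 3
        others = [c for c in baltimore.monitor_cells if c.coords != (6, 6)]
        assert all(c.n_monitors == 1 for c in others)

    def test_health_data_coverage(self, baltimore):
        with_health = [c for c in baltimore.cells if c.has_health_data]
        assert len(with_health) == 72
        # every monitor cell has health data; 57 of 84 no-monitor cells do
        assert all(c.has_health_data for c in baltimore.monitor_cells)
        assert sum(1 for c in with_health if not c.has_monitor) == 57

    def test_jurisdiction_monitor_totals(self, baltimore):
        by_jur = {}
        for c in baltimore.monitor_cells:
            by_jur[c.jurisdiction] = by_jur.get(c.jurisdiction, 0) + c.n_monitors
        assert by_jur == {"BC": 6, "AA": 4, "PG": 3, "B": 2, "M": 1, "H": 1}


class TestCanonicalOrder:
    def test_monitor_subset_head(self, baltimore):
        first5 = [c.coords for c in canonical_order(baltimore, "Yes")[:5]]
        assert first5 == [(8, 6), (8, 8), (7, 5), (7, 6), (7, 7)]

    def test_predecessor_in_full_ordering(self, baltimore):
        order = [c.coords for c in canonical_order(baltimore, "Both")]
        assert order[order.index((9, 7)) - 1] == (9, 6)

    @pytest.mark.parametrize("condition", CONDITIONS)
    def test_ordering_is_permutation(self, baltimore, condition):
        order = canonical_order(baltimore, condition)
        assert len(order) == len(set(order)) == len(baltimore.subset(condition))

    def test_empty_subset_errors(self):
        cells = tuple(GridCell(r, c) for r in (1, 2) for c in (1, 2))
        lat = Lattice(2, 2, cells)
        with pytest.raises(LatticeError, match="selects no cells"):
            canonical_order(lat, "Yes")


class TestLagAssignment:
    @pytest.mark.parametrize(
        "index,condition,expected",
        [
            ((9, 7), "No", [(9, 6), (9, 5), (9, 4), (9, 3)]),
            ((6, 7), "Yes", [(6, 6), (7, 7), (7, 6), (7, 5)]),
            ((4, 7), "Both", [(4, 6), (4, 5), (4, 4), (4, 3)]),
        ],
    )
    def test_published_worked_sequences(self, baltimore, index, condition, expected):
        seq = assign_lag_grids(baltimore, index, condition)
        assert [c.coords for c in seq.lag_cells] == expected

    @pytest.mark.parametrize("row", [2, 5, 10])
    def test_column4_wraps_to_column9_next_row_north(self, baltimore, row):
        seq = assign_lag_grids(baltimore, (row, 4), "Both")
        assert seq.lag_cells[3].coords == (row + 1, 9)
        assert seq.wrapped == (False, False, False, True)

    def test_ring_roundtrip_every_cell(self, baltimore):
        """Stepping 4 positions forward from lag 4 recovers the index cell."""
        for condition in CONDITIONS:
            order = canonical_order(baltimore, condition)
            for cell in order:
                seq = assign_lag_grids(baltimore, cell, condition)
                pos4 = order.index(seq.lag_cells[3])
                assert order[(pos4 + 4) % len(order)] is cell

    def test_start_of_ordering_wraps_around_lattice(self, baltimore):
        seq = assign_lag_grids(baltimore, (11, 1), "Both")
        assert seq.wrapped_around_lattice
        assert [c.coords for c in seq.lag_cells] == [(1, 9), (1, 8), (1, 7), (1, 6)]

    def test_index_outside_subset_errors(self, baltimore):
        with pytest.raises(LatticeError, match="Yes"):
            assign_lag_grids(baltimore, (9, 7), "Yes")


class TestPrecedeFollow:
    @pytest.mark.parametrize(
        "index,expected",
        [
            ((5, 3), ("precede", "precede", "follow", "follow")),
            ((5, 1), ("follow", "follow", "follow", "follow")),
            ((5, 5), ("precede",) * 4),
        ],
    )
    def test_column_position_sets_direction_split(self, baltimore, index, expected):
        seq = assign_lag_grids(baltimore, index, "Both")
        assert classify_precede_follow(seq) == expected

    def test_no_monitor_row_interior_all_precede(self, baltimore):
        seq = assign_lag_grids(baltimore, (9, 7), "No")
        assert classify_precede_follow(seq) == ("precede",) * 4

    def test_percentages_sum_to_100(self, baltimore):
        for condition in CONDITIONS:
            pct = precede_follow_percentages(baltimore, condition)
            assert pct["precede"] + pct["follow"] == pytest.approx(100.0)
            assert pct["precede"] >= 0 and pct["follow"] >= 0
        # dense subsets select mostly same-row (westward, preceding) lag cells
        both = precede_follow_percentages(baltimore, "Both")
        assert both["precede"] > both["follow"]

    def test_observation_weights_change_tabulation(self, baltimore):
        unweighted = precede_follow_percentages(baltimore, "Both")
        weighted = precede_follow_percentages(
            baltimore, "Both", weights={(5, 1): 1.0}
        )
        assert weighted["follow"] == pytest.approx(100.0)
        assert weighted != unweighted


class TestPointAssignment:
    def test_cell_center_and_west_edge(self, baltimore):
        # center of cell (5,5): x in [48,60), y in [48,60)
        assert assign_point_to_grid(baltimore, 54.0, 54.0).coords == (5, 5)
        assert assign_point_to_grid(baltimore, 48.0, 54.0).coords == (5, 5)

    def test_partition_against_brute_force(self, baltimore, rng):
        """Every random point maps to exactly one cell (containment oracle)."""
        w, h = baltimore.cell_width_km, baltimore.cell_height_km
        xs = rng.uniform(0, baltimore.n_cols * w, size=1000)
        ys = rng.uniform(0, baltimore.n_rows * h, size=1000)
        for x, y in zip(xs, ys):
            containing = [
                c.coords
                for c in baltimore.cells
                if (c.col - 1) * w <= x < c.col * w and (c.row - 1) * h <= y < c.row * h
            ]
            assert len(containing) == 1
            assert assign_point_to_grid(baltimore, x, y).coords == containing[0]

    def test_outside_lattice_errors(self, baltimore):
        with pytest.raises(LatticeError, match="outside"):
            assign_point_to_grid(baltimore, -1.0, 5.0)
        with pytest.raises(LatticeError, match="outside"):
            assign_point_to_grid(baltimore, 5.0, 11 * 12.0)


class TestGeometryAndCounts:
    @pytest.mark.parametrize(
        "n,expected", [(5, (60.0, 720.0)), (2, (24.0, 288.0)), (0, (0.0, 0.0))]
    )
    def test_hosa_geometry_examples(self, n, expected):
        assert hosa_geometry(n) == expected

    @given(st.integers(min_value=0, max_value=50))
    def test_hosa_geometry_linear_multiple_of_144(self, n):
        km, km2 = hosa_geometry(n)
        assert km == 12.0 * n
        assert km2 == 144.0 * n

    def test_negative_grids_error(self):
        with pytest.raises(LatticeError):
            hosa_geometry(-1)

    @pytest.mark.parametrize(
        "args,expected",
        [((3, 4, 7, 99), 8316), ((3, 4, 7, 15), 1260), ((3, 4, 7, 84), 7056),
         ((1, 1, 1, 1), 1)],
    )
    def test_design_combination_counts(self, args, expected):
        assert count_design_combinations(*args) == expected

    def test_lag_label_normalization(self):
        assert canonical_lag_label(1) == "1"
        assert lag_span("01") == (0, 1)
        assert lag_span("24") == (2, 3, 4)
        with pytest.raises(LatticeError):
            canonical_lag_label("05")


def test_lattice_csv_roundtrip(baltimore, tmp_path):
    path = tmp_path / "lattice.csv"
    write_lattice(baltimore, path)
    again = read_lattice(path)
    assert again == baltimore
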