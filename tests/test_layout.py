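"""Layout engine: serpentine order, numbering, matrix building, validation."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plotgrid import (
    CellRole,
    LayoutError,
    ReplicatedSpec,
    UnreplicatedSpec,
    build_matrix_replicated,
    build_matrix_unreplicated,
    replicated_plot_number,
    serpentine_cell_sequence,
    validate_spec,
)


def brute_force_serpentine(rows, ranges, right_to_left):
    """Independent enumeration: list each range, reverse odd ones explicitly."""
    out = []
    for g in range(ranges):
        block = [(r, g) for r in range(rows)]
        if g % 2 == 1:
            block = list(reversed(block))
        if right_to_left:
            block = [(rows - 1 - r, g) for r, g in block]
        out.extend(block)
    return out


class TestSerpentine:
    @pytest.mark.parametrize(
        "rows,ranges,rtl,expected",
        [
            (1, 1, False, [(0, 0)]),
            (4, 2, False,
             [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1), (2, 1), (1, 1), (0, 1)]),
            (4, 2, True,
             [(3, 0), (2, 0), (1, 0), (0, 0), (0, 1), (1, 1), (2, 1), (3, 1)]),
        ],
    )
    def test_known_sequences(self, rows, ranges, rtl, expected):
        assert serpentine_cell_sequence(rows, ranges, rtl) == expected

    @pytest.mark.parametrize("rtl", [False, True])
    def test_matches_brute_force_up_to_8x8(self, rtl):
        for rows in range(1, 9):
            for ranges in range(1, 9):
                assert serpentine_cell_sequence(rows, ranges, rtl) == \
                    brute_force_serpentine(rows, ranges, rtl)

    @given(rows=st.integers(1, 12), ranges=st.integers(1, 12))
    def test_mirror_property(self, rows, ranges):
        """right_to_left at (r, g) equals left_to_right at (rows-1-r, g)."""
        ltr = serpentine_cell_sequence(rows, ranges, False)
        rtl = serpentine_cell_sequence(rows, ranges, True)
        assert rtl == [(rows - 1 - r, g) for r, g in ltr]

    @given(rows=st.integers(1, 12), ranges=st.integers(1, 12),
           rtl=st.booleans())
    def test_covers_grid_and_is_adjacent(self, rows, ranges, rtl):
        seq = serpentine_cell_sequence(rows, ranges, rtl)
        assert len(seq) == rows * ranges
        assert len(set(seq)) == rows * ranges
        assert all(0 <= g2 - g1 <= 1 for (_, g1), (_, g2) in zip(seq, seq[1:]))
        for (r1, g1), (r2, g2) in zip(seq, seq[1:]):
            assert abs(r1 - r2) + abs(g1 - g2) == 1  # grid-adjacent steps

    def test_rejects_non_positive_dimensions(self):
        with pytest.raises(LayoutError):
            serpentine_cell_sequence(0, 3)
        with pytest.raises(LayoutError):
            serpentine_cell_sequence(3, -1)


class TestReplicatedNumbering:
    @pytest.mark.parametrize(
        "rep,within,ppr,expected",
        [
            (3, 20, 20, 320),     # two trailing digits below 100 plots/rep
            (1, 1, 200, 1001),    # three digits at 100-999 plots/rep
            (1, 1, 1, 101),       # smallest design still uses two digits
            (2, 137, 200, 2137),
            (1, 1, 1000, 10001),  # four digits past 999 plots/rep
        ],
    )
    def test_prefix_scheme(self, rep, within, ppr, expected):
        assert replicated_plot_number(rep, within, ppr) == expected

    def test_rejects_out_of_range_index(self):
        with pytest.raises(LayoutError):
            replicated_plot_number(1, 21, 20)
        with pytest.raises(LayoutError):
            replicated_plot_number(1, 0, 20)


class TestReplicatedMatrix:
    def test_yield_trial_role_counts(self, yield_trial_case):
        m = build_matrix_replicated(yield_trial_case.spec)
        assert m.role_count(CellRole.EXPERIMENTAL) == 90
        assert m.role_count(CellRole.FILL) == 6
        assert m.role_count(CellRole.WHEEL_TRACK) == 8
        assert m.role_count(CellRole.EXCLUDED) == 0

    def test_one_full_range(self):
        spec = ReplicatedSpec(plots_per_rep=2, reps=1, rows=2, ranges=1,
                              fills_after_reps=(0,))
        m = build_matrix_replicated(spec)
        assert m[(0, 0)].plot_number == 101
        assert m[(1, 0)].plot_number == 102
        assert all(c.role is CellRole.EXPERIMENTAL for c in m.cells.values())

    def test_hand_walked_grid_with_wheel_track(self):
        """2x4 grid, 2 reps x 2 plots, one fill each, range 2 a wheel track.

        Serpentine walk: 101,102 | W,W | F,201 | 202,F (last range reversed).
        """
        spec = ReplicatedSpec(plots_per_rep=2, reps=2, rows=2, ranges=4,
                              fills_after_reps=(1, 1), wheel_track_ranges=(2,))
        m = build_matrix_replicated(spec)
        assert (m[(0, 0)].plot_number, m[(1, 0)].plot_number) == (101, 102)
        assert m[(0, 1)].role is CellRole.WHEEL_TRACK
        assert m[(1, 1)].role is CellRole.WHEEL_TRACK
        assert m[(0, 2)].role is CellRole.FILL and m[(0, 2)].rep_number == 1
        assert m[(1, 2)].plot_number == 201
        assert m[(1, 3)].plot_number == 202
        assert m[(0, 3)].role is CellRole.FILL and m[(0, 3)].rep_number == 2

    def test_wheel_track_ranges_have_no_numbers(self, yield_trial_case):
        m = build_matrix_replicated(yield_trial_case.spec)
        for g in (8, 17):  # 1-based ranges 9 and 18
            for r in range(4):
                assert m[(r, g)].role is CellRole.WHEEL_TRACK
                assert m[(r, g)].plot_number is None

    def test_numbers_unique_and_contiguous_per_rep(self, yield_trial_case):
        m = build_matrix_replicated(yield_trial_case.spec)
        nums = m.plot_numbers()
        assert len(nums) == len(set(nums)) == 90
        assert set(nums) == {r * 100 + i for r in (1, 2, 3) for i in range(1, 31)}

    def test_count_mismatch_names_both_values(self):
        spec = ReplicatedSpec(plots_per_rep=25, reps=4, rows=4, ranges=26,
                              fills_after_reps=(0, 0, 0, 0))
        with pytest.raises(LayoutError, match=r"100.*104"):
            build_matrix_replicated(spec)

    def test_count_conservation_random_specs(self):
        """Roles partition the grid for 200 random valid replicated specs."""
        rng = random.Random(42)
        for _ in range(200):
            rows = rng.randint(1, 6)
            ranges = rng.randint(1, 20)
            wheel = tuple(sorted(rng.sample(range(1, ranges + 1),
                                            rng.randint(0, min(3, ranges - 1)))))
            capacity = rows * (ranges - len(wheel))
            if capacity < 1:
                continue
            reps = rng.randint(1, min(4, capacity))
            ppr = rng.randint(1, capacity // reps)
            slack = capacity - reps * ppr
            fills = [0] * reps
            for _ in range(slack):
                fills[rng.randrange(reps)] += 1
            spec = ReplicatedSpec(plots_per_rep=ppr, reps=reps, rows=rows,
                                  ranges=ranges, fills_after_reps=tuple(fills),
                                  wheel_track_ranges=wheel,
                                  right_to_left=rng.random() < 0.5)
            assert validate_spec(spec) == []
            m = build_matrix_replicated(spec)
            assert m.role_count(CellRole.EXPERIMENTAL) == reps * ppr
            assert m.role_count(CellRole.FILL) == slack
            assert m.role_count(CellRole.WHEEL_TRACK) == rows * len(wheel)
            assert len(m.cells) == rows * ranges
            nums = m.plot_numbers()
            assert len(nums) == len(set(nums))

    def test_wheel_track_neutrality(self):
        """Dropping wheel-track ranges leaves the walk-order numbering intact."""
        spec = ReplicatedSpec(plots_per_rep=10, reps=2, rows=4, ranges=8,
                              fills_after_reps=(2, 2), wheel_track_ranges=(3, 6))
        bare = ReplicatedSpec(plots_per_rep=10, reps=2, rows=4, ranges=6,
                              fills_after_reps=(2, 2))
        assert build_matrix_replicated(spec).plot_numbers() == \
            build_matrix_replicated(bare).plot_numbers()


class TestUnreplicatedMatrix:
    def test_nursery_set1(self):
        spec = UnreplicatedSpec(start_plot=1, end_plot=701, rows=52, ranges=14)
        m = build_matrix_unreplicated(spec)
        assert m.role_count(CellRole.EXPERIMENTAL) == 701
        assert m.role_count(CellRole.EXCLUDED) == 27
        assert set(m.plot_numbers()) == set(range(1, 702))

    def test_single_cell(self):
        m = build_matrix_unreplicated(
            UnreplicatedSpec(start_plot=5, end_plot=5, rows=1, ranges=1))
        assert m[(0, 0)].plot_number == 5

    def test_indented_right_to_left_layout(self):
        spec = UnreplicatedSpec(start_plot=1, end_plot=1067, rows=52, ranges=34,
                                plot_indent=25, right_to_left=True)
        m = build_matrix_unreplicated(spec)
        assert m.role_count(CellRole.EXPERIMENTAL) == 1067
        # excluded cells = 25 indent cells + trailing slack
        assert m.role_count(CellRole.EXCLUDED) == 52 * 34 - 1067
        # first 25 serpentine cells (rightmost rows of the front range) skipped
        assert m[(51, 0)].role is CellRole.EXCLUDED
        assert m[(51 - 25, 0)].plot_number == 1
        # numbering runs serpentine: plot numbers ascend along the walk
        assert m.plot_numbers() == list(range(1, 1068))

    def test_exactly_filled_extent_is_allowed(self):
        spec = UnreplicatedSpec(start_plot=1068, end_plot=2783, rows=52, ranges=33)
        assert validate_spec(spec) == []
        m = build_matrix_unreplicated(spec)
        assert m.role_count(CellRole.EXCLUDED) == 0

    def test_capacity_error(self):
        spec = UnreplicatedSpec(start_plot=1, end_plot=10, rows=3, ranges=3)
        with pytest.raises(LayoutError, match="exceeds"):
            build_matrix_unreplicated(spec)


class TestValidateSpec:
    def test_valid_yield_trial_has_no_issues(self, yield_trial_case):
        assert validate_spec(yield_trial_case.spec) == []

    def test_fills_length_mismatch_cites_reps(self):
        spec = ReplicatedSpec(plots_per_rep=30, reps=3, rows=4, ranges=26,
                              fills_after_reps=(2, 2), wheel_track_ranges=(9, 18))
        issues = validate_spec(spec)
        assert len(issues) == 1
        assert "Reps" in issues[0] and "Fills" in issues[0]

    def test_count_mismatch_reports_both_counts(self):
        spec = ReplicatedSpec(plots_per_rep=25, reps=4, rows=4, ranges=26,
                              fills_after_reps=(0, 0, 0, 0))
        issues = validate_spec(spec)
        assert len(issues) == 1
        assert "100" in issues[0] and "104" in issues[0]

    def test_wheel_track_out_of_range(self):
        spec = ReplicatedSpec(plots_per_rep=4, reps=1, rows=2, ranges=3,
                              fills_after_reps=(0,), wheel_track_ranges=(4,))
        assert any("Wheel track" in i for i in validate_spec(spec))

    def test_indent_must_be_smaller_than_rows(self):
        spec = UnreplicatedSpec(start_plot=1, end_plot=4, rows=3, ranges=3,
                                plot_indent=3)
        assert any("indent" in i.lower() for i in validate_spec(spec))

    def test_end_before_start(self):
        spec = UnreplicatedSpec(start_plot=10, end_plot=5, rows=3, ranges=3)
        assert any("Start plot" in i for i in validate_spec(spec))
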