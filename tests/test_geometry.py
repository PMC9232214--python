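"""Unit tests for the overlap-computation pipeline stages."""

from __future__ import annotations

import numpy as np
import pytest

from painmap import (
    ContractError,
    DrawingSet,
    IntervalWindow,
    InvalidRecordingError,
    MaskError,
    PainRecording,
    apply_null_mask,
    boundaries,
    compute_overlap,
    compute_overlap_by_region,
    filter_map,
    merge_cells,
    overlap_grid,
    partitions,
)

from conftest import make_set


def rec(p, x, y, w, h, **kw):
    return PainRecording(p, x, y, w, h, **kw)


class TestBoundaries:
    @pytest.mark.parametrize(
        "rows, axis, expected",
        [
            ([("a", 5, 0, 20, 5)], "x", [5, 25]),
            (
                [("a", 0, 0, 30, 5), ("b", 20, 0, 30, 5), ("c", 10, 0, 30, 5)],
                "x",
                [0, 10, 20, 30, 40, 50],
            ),
            # shared edge of abutting rectangles is deduplicated
            ([("a", 0, 0, 10, 5), ("b", 10, 0, 10, 5)], "x", [0, 10, 20]),
            ([("a", 5, 7, 20, 13)], "y", [7, 20]),
            ([], "x", []),
        ],
    )
    def test_edge_collection(self, rows, axis, expected):
        recs = [rec(*r) for r in rows]
        assert boundaries(recs, axis) == expected

    def test_invalid_axis(self):
        with pytest.raises(ContractError):
            boundaries([], "z")

    def test_degenerate_recording_rejected(self):
        with pytest.raises(InvalidRecordingError):
            rec("a", 0, 0, 0, 10)
        with pytest.raises(InvalidRecordingError):
            rec("a", 0, 0, 10, -1)


class TestPartitions:
    @pytest.mark.parametrize(
        "bounds, expected",
        [
            ([0, 10, 20], [(0, 10), (10, 20)]),
            ([5, 25], [(5, 25)]),
            ([], []),
        ],
    )
    def test_windows(self, bounds, expected):
        assert partitions(bounds) == [IntervalWindow(*w) for w in expected]

    def test_windows_tile_range(self):
        wins = partitions([0.5, 1.25, 7, 19.5])
        assert wins[0].start == 0.5 and wins[-1].end == 19.5
        for w0, w1 in zip(wins, wins[1:]):
            assert w0.end == w1.start

    @pytest.mark.parametrize("bad", [[1, 0], [0, 0, 1], [0, 2, 1]])
    def test_unsorted_or_duplicated_rejected(self, bad):
        with pytest.raises(ContractError):
            partitions(bad)


class TestOverlapGrid:
    def test_two_square_cells(self, two_square):
        grid = overlap_grid(two_square.recordings)
        assert len(grid) == 7
        sets = dict(grid.items())
        assert sets[(1, 1)] == frozenset({"a", "b"})
        singles = [s for cell, s in sets.items() if cell != (1, 1)]
        assert all(len(s) == 1 for s in singles)

    def test_empty_cell_is_absent(self, two_square):
        grid = overlap_grid(two_square.recordings)
        with pytest.raises(KeyError):
            grid[(0, 2)]  # top-right corner cell covered by neither square
        assert (0, 2) not in grid

    def test_same_participant_counts_once(self):
        ds = make_set([("a", 0, 0, 20, 20), ("a", 10, 10, 20, 20)])
        grid = overlap_grid(ds.recordings)
        assert all(s == frozenset({"a"}) for s in grid.values())

    def test_disjoint_rects_never_share_cells(self):
        ds = make_set([("a", 0, 0, 10, 10), ("b", 50, 50, 10, 10)])
        grid = overlap_grid(ds.recordings)
        assert all(len(s) == 1 for s in grid.values())

    def test_window_consistency_contract(self, two_square):
        xw = partitions(boundaries(two_square.recordings, "x"))
        yw = partitions(boundaries(two_square.recordings, "y"))
        grid = overlap_grid(two_square.recordings, xw, yw)
        assert len(grid) == 7
        with pytest.raises(ContractError):
            overlap_grid(two_square.recordings, xw[:-1], yw)


class TestMergeCells:
    @pytest.mark.parametrize("layout", ["horizontal", "vertical"])
    def test_nested_three_participants_gives_nine(self, concentric3, layout):
        rects = merge_cells(overlap_grid(concentric3.recordings), layout)
        assert len(rects) == 9
        by_freq = sorted(r.overlap_frequency for r in rects)
        assert by_freq == [1, 1, 1, 1, 2, 2, 2, 2, 3]

    @pytest.mark.parametrize("layout", ["horizontal", "vertical"])
    def test_nested_single_participant_collapses(self, nested_single, layout):
        rects = merge_cells(overlap_grid(nested_single.recordings), layout)
        assert len(rects) == 1
        r = rects[0]
        assert (r.x, r.y, r.width, r.height) == (20.0, 20.0, 60.0, 60.0)

    def test_two_square_horizontal(self, two_square):
        rects = merge_cells(
            overlap_grid(two_square.recordings), "horizontal", total_drawings=2
        )
        assert len(rects) == 5
        (both,) = [r for r in rects if r.overlap == frozenset({"a", "b"})]
        assert (both.x, both.y, both.width, both.height) == (10.0, 10.0, 10.0, 10.0)


class TestComputeOverlap:
    def test_complete_overlay(self):
        ds = make_set([("a", 5, 5, 10, 10), ("b", 5, 5, 10, 10)], total_drawings=2)
        fm = compute_overlap(ds)
        assert len(fm) == 1
        assert fm.rects[0].overlap_frequency == 2
        assert fm.rects[0].overlap_proportion == 1.0

    def test_three_way_proportions(self, venn3):
        fm = compute_overlap(venn3)
        props = {r.overlap_frequency: r.overlap_proportion for r in fm}
        assert props[1] == pytest.approx(1 / 3)
        assert props[2] == pytest.approx(2 / 3)
        assert props[3] == pytest.approx(3 / 3)

    def test_empty_drawings_in_denominator(self):
        # one participant drew, two submitted empty drawings: T = 3
        ds = make_set([("a", 0, 0, 10, 10)], total_drawings=3)
        fm = compute_overlap(ds)
        assert len(fm) == 1
        assert fm.rects[0].overlap_proportion == pytest.approx(1 / 3)

    def test_participant_denominator_flag(self):
        ds = make_set([("a", 0, 0, 10, 10)], total_drawings=3)
        fm = compute_overlap(ds, denominator="participants")
        assert fm.rects[0].overlap_proportion == 1.0

    def test_no_recordings_gives_empty_map(self):
        ds = DrawingSet([], total_drawings=4, region="front")
        fm = compute_overlap(ds)
        assert len(fm) == 0 and fm.max_frequency is None

    def test_more_participants_than_drawings_rejected(self):
        with pytest.raises(ContractError):
            make_set([("a", 0, 0, 1, 1), ("b", 5, 5, 1, 1)], total_drawings=1)

    def test_output_sorted_by_y_then_x(self, venn3):
        fm = compute_overlap(venn3)
        keys = [(r.y, r.x) for r in fm]
        assert keys == sorted(keys)

    def test_regions_processed_alphabetically(self):
        front = make_set([("a", 0, 0, 5, 5)], region="front")
        back = make_set([("b", 0, 0, 5, 5)], region="back")
        maps = compute_overlap_by_region([front, back])
        assert [fm.region for fm in maps] == ["back", "front"]


class TestFilterMap:
    def test_min_frequency_keeps_shared_rect(self, two_square):
        fm = filter_map(compute_overlap(two_square), min_freq=2)
        assert len(fm) == 1
        assert fm.rects[0].overlap == frozenset({"a", "b"})

    def test_identity_filter(self, venn3):
        fm = compute_overlap(venn3)
        out = filter_map(fm, min_freq=1, max_freq=fm.max_frequency)
        assert len(out) == len(fm)
        assert [(r.x, r.y) for r in out] == [(r.x, r.y) for r in fm]

    def test_width_threshold_can_empty_the_map(self, two_square):
        fm = compute_overlap(two_square)
        assert len(filter_map(fm, min_width=1000.0)) == 0

    def test_proportion_denominator_unchanged(self, two_square):
        fm = filter_map(compute_overlap(two_square), min_freq=2)
        assert fm.rects[0].overlap_proportion == pytest.approx(1.0)

    def test_inverted_range_rejected(self, two_square):
        with pytest.raises(ContractError):
            filter_map(compute_overlap(two_square), min_freq=3, max_freq=1)


class TestNullMask:
    def _masked(self):
        ds = make_set(
            [("N", 0, 0, 100, 100), ("A", 10, 10, 10, 10)], total_drawings=2
        )
        return apply_null_mask(compute_overlap(ds), "N")

    def test_retains_shared_rects_only(self):
        fm = self._masked()
        assert all(r.overlap == frozenset({"A"}) for r in fm)
        assert float(fm.areas.sum()) == 100.0

    def test_frequency_and_denominator_adjusted(self):
        fm = self._masked()
        assert fm.rects[0].overlap_frequency == 1
        assert fm.rects[0].overlap_proportion == 1.0  # denominator excludes null

    def test_no_real_overlap_gives_empty_map(self):
        # real drawing entirely outside the null template
        ds = make_set(
            [("N", 0, 0, 50, 50), ("A", 200, 200, 10, 10)], total_drawings=2
        )
        fm = apply_null_mask(compute_overlap(ds), "N")
        assert len(fm) == 0

    def test_absent_null_id_rejected(self, two_square):
        with pytest.raises(MaskError):
            apply_null_mask(compute_overlap(two_square), "nope")
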