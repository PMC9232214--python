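"""Property-based invariants of the overlap decomposition.

All properties are exercised on random integer instances, where the
pixel oracle provides exact ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painmap import DrawingSet, PainRecording, compute_overlap

from conftest import assert_map_matches_oracle, assert_maximal, make_set


def recordings_strategy(max_participants=6, max_rects=25, extent=60, max_size=30):
    participant = st.integers(0, max_participants - 1).map(lambda i: f"p{i}")
    record = st.tuples(
        participant,
        st.integers(0, extent - 1),
        st.integers(0, extent - 1),
        st.integers(1, max_size),
        st.integers(1, max_size),
    )
    return st.lists(record, min_size=1, max_size=max_rects).map(
        lambda rows: make_set([(p, float(x), float(y), float(w), float(h)) for p, x, y, w, h in rows])
    )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(ds=recordings_strategy(), layout=st.sampled_from(["horizontal", "vertical"]))
def test_oracle_equivalence_disjointness_conservation(ds, layout):
    """Output tiles the drawn area exactly with the right participant sets."""
    fm = compute_overlap(ds, layout=layout)
    assert_map_matches_oracle(ds, fm)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(ds=recordings_strategy(), layout=st.sampled_from(["horizontal", "vertical"]))
def test_maximality(ds, layout):
    """No two same-set output rectangles remain merge-eligible."""
    assert_maximal(compute_overlap(ds, layout=layout))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(ds=recordings_strategy())
def test_layout_invariance_of_per_set_areas(ds):
    """Horizontal and vertical layouts tile the same regions: per-set
    total areas agree although rectangle counts may differ."""
    fh = compute_overlap(ds, layout="horizontal")
    fv = compute_overlap(ds, layout="vertical")
    assert fh.area_by_overlap_set() == fv.area_by_overlap_set()


@settings(max_examples=40, derandomize=True, deadline=None)
@given(ds=recordings_strategy(), seed=st.integers(0, 2**16))
def test_permutation_invariance(ds, seed):
    """Shuffling input rows leaves (overlap set, total area) pairs unchanged."""
    rng = np.random.default_rng(seed)
    shuffled = list(ds.recordings)
    rng.shuffle(shuffled)
    ds2 = DrawingSet.from_recordings(shuffled, ds.total_drawings, ds.region)
    assert (
        compute_overlap(ds).area_by_overlap_set()
        == compute_overlap(ds2).area_by_overlap_set()
    )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(ds=recordings_strategy())
def test_frequency_bounds_and_proportion_law(ds):
    """1 <= |o| <= |P| and proportion * T == frequency exactly."""
    fm = compute_overlap(ds)
    n_p = len(ds.participants)
    for r in fm:
        assert 1 <= r.overlap_frequency <= n_p
        assert r.overlap_proportion * fm.denominator == r.overlap_frequency

    fm2 = compute_overlap(ds, denominator="participants")
    for r in fm2:
        assert r.overlap_proportion * n_p == r.overlap_frequency


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    depth=st.integers(1, 6),
    x0=st.integers(0, 50),
    y0=st.integers(0, 50),
    layout=st.sampled_from(["horizontal", "vertical"]),
)
def test_nested_single_participant_law(depth, x0, y0, layout):
    """One participant's strictly nested rectangles collapse to exactly
    the outermost rectangle."""
    side = 4 * depth + 2
    rows = [
        ("solo", float(x0 + 2 * i), float(y0 + 2 * i), float(side - 4 * i), float(side - 4 * i))
        for i in range(depth)
    ]
    fm = compute_overlap(make_set(rows), layout=layout)
    assert len(fm) == 1
    r = fm.rects[0]
    assert (r.x, r.y, r.width, r.height) == (float(x0), float(y0), float(side), float(side))


def test_float_coordinates_supported():
    """Real-valued coordinates pass through without rounding."""
    ds = make_set([("a", 0.25, 0.5, 1.75, 2.25), ("b", 1.0, 1.0, 2.5, 0.125)])
    fm = compute_overlap(ds)
    total = fm.areas.sum()
    # union area via inclusion-exclusion on the two boxes
    inter_w = max(0.0, min(0.25 + 1.75, 1.0 + 2.5) - 1.0)
    inter_h = max(0.0, min(0.5 + 2.25, 1.0 + 0.125) - 1.0)
    expected = 1.75 * 2.25 + 2.5 * 0.125 - inter_w * inter_h
    assert total == pytest.approx(expected, rel=1e-12)
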