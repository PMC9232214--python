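from __future__ import annotations

import numpy as np
import pytest

from painmap import (
    DrawingSet,
    FrequencyMap,
    PainRecording,
    fixtures,
    rasterize_oracle,
)


@pytest.fixture
def two_square() -> DrawingSet:
    return fixtures("two_square")


@pytest.fixture
def concentric3() -> DrawingSet:
    return fixtures("concentric3")


@pytest.fixture
def nested_single() -> DrawingSet:
    return fixtures("nested_single")


@pytest.fixture
def venn3() -> DrawingSet:
    return fixtures("venn3")


def make_set(rows, total_drawings=None, region="front") -> DrawingSet:
    """Build a DrawingSet from (participant, x, y, w, h) tuples."""
    recs = [
        PainRecording(p, x, y, w, h, region, order=i)
        for i, (p, x, y, w, h) in enumerate(rows)
    ]
    return DrawingSet.from_recordings(recs, total_drawings, region)


def random_drawing_set(
    rng: np.random.Generator,
    max_participants: int = 10,
    max_rects: int = 100,
    extent: int = 200,
    max_size: int = 60,
) -> DrawingSet:
    """Random integer-coordinate instance on [0, extent)^2."""
    n_participants = int(rng.integers(1, max_participants + 1))
    n_rects = int(rng.integers(1, max_rects + 1))
    rows = []
    for _ in range(n_rects):
        p = f"p{int(rng.integers(n_participants)):02d}"
        x = int(rng.integers(0, extent))
        y = int(rng.integers(0, extent))
        w = int(rng.integers(1, max_size + 1))
        h = int(rng.integers(1, max_size + 1))
        rows.append((p, float(x), float(y), float(w), float(h)))
    return make_set(rows)


def assert_map_matches_oracle(ds: DrawingSet, fm: FrequencyMap) -> None:
    """Per-pixel equivalence of a frequency map with the raster oracle.

    Checks (on integer instances): output rectangles are pairwise
    disjoint, their per-pixel participant sets equal the brute-force
    rasterization everywhere (so the union area is conserved exactly),
    and per-overlap-set total areas match.
    """
    po = rasterize_oracle(ds.recordings)
    w, h = po.shape
    predicted = np.zeros((w, h), np.uint64)
    coverage = np.zeros((w, h), np.int32)
    for r in fm.rects:
        x0, y0 = int(r.x) - po.x0, int(r.y) - po.y0
        x1, y1 = x0 + int(r.width), y0 + int(r.height)
        assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h
        predicted[x0:x1, y0:y1] |= np.uint64(po.bitmask_of(r.overlap))
        coverage[x0:x1, y0:y1] += 1
    assert coverage.max(initial=0) <= 1, "output rectangles overlap"
    assert np.array_equal(predicted, po.bits), "per-pixel participant sets differ"
    assert float(fm.areas.sum()) == float(po.covered_area()), "area not conserved"
    oracle_areas = {k: float(v) for k, v in po.area_by_set().items()}
    assert fm.area_by_overlap_set() == oracle_areas


def assert_maximal(fm: FrequencyMap) -> None:
    """No two same-overlap rectangles satisfy a merge-eligibility rule:
    equal y-extent and x-adjacent, or equal x-extent and y-adjacent."""
    rects = fm.rects
    for i, r1 in enumerate(rects):
        for r2 in rects[i + 1 :]:
            if r1.overlap != r2.overlap:
                continue
            same_y = r1.y == r2.y and r1.height == r2.height
            same_x = r1.x == r2.x and r1.width == r2.width
            x_adjacent = r1.x + r1.width == r2.x or r2.x + r2.width == r1.x
            y_adjacent = r1.y + r1.height == r2.y or r2.y + r2.height == r1.y
            assert not (same_y and x_adjacent), f"mergeable along x: {r1}, {r2}"
            assert not (same_x and y_adjacent), f"mergeable along y: {r1}, {r2}"
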