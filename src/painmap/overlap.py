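"""Rectangle overlap decomposition: the overlap-computation algorithm.

Given any number of participants' overlapping axis-aligned rectangles on
a 2D template, decompose the union into *disjoint* rectangles, each
labelled with the set of distinct participants covering it:

1. **decomposition** — collect every rectangle edge coordinate along
   each axis;
2. **partitions** — consecutive distinct edges become half-open interval
   windows; x- and y-windows cross to form grid cells;
3. **overlap grid** — each covered cell is assigned the set of distinct
   participants with at least one rectangle containing it (set
   semantics: several marks by one participant count once);
4. **merging** — adjacent cells with identical overlap sets are fused
   into maximal rectangles, preferring width (horizontal layout) or
   height (vertical layout).

The merge is two passes: pass 1 fuses maximal runs of adjacent cells
with equal overlap sets along the layout axis within each cross-axis
band; pass 2 fuses pass-1 results that have equal overlap sets, equal
layout-axis extent, and are edge-adjacent on the cross axis, to a
fixpoint. The result tiles the covered area exactly and is maximal
under both rules; three nested squares by three participants yield
nine rectangles (centre plus four per ring), by one participant a
single rectangle.

Internally the grid is columnar: each participant's coverage is added
to per-cell 128-bit blake2b key sums and a distinct-participant count,
so cells with equal (count, keysum) carry equal participant sets; the
actual member sets are then recovered per distinct label and verified
against the counts (a key collision, probability ~2^-128 per pair,
raises rather than corrupting output).
"""

from __future__ import annotations

import hashlib
import struct
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np

from .model import (
    ContractError,
    DrawingSet,
    FrequencyMap,
    IntervalWindow,
    InvalidRecordingError,
    Layout,
    MaskError,
    OutputRect,
    PainRecording,
)

__all__ = [
    "boundaries",
    "partitions",
    "overlap_grid",
    "OverlapGrid",
    "merge_cells",
    "compute_overlap",
    "compute_overlap_by_region",
    "filter_map",
    "apply_null_mask",
]


def boundaries(
    recordings: Sequence[PainRecording], axis: Literal["x", "y"]
) -> list[float]:
    """Sorted, deduplicated edge coordinates of all recordings along one axis.

    For axis ``"x"`` the edges are {x, x+width}; for ``"y"``, {y, y+height}.
    Empty input gives an empty list.
    """
    if axis not in ("x", "y"):
        raise ContractError(f"axis must be 'x' or 'y', got {axis!r}")
    edges: set[float] = set()
    for r in recordings:
        if not (r.width > 0 and r.height > 0):
            raise InvalidRecordingError(
                f"recording for {r.participant!r} has non-positive size"
            )
        if axis == "x":
            edges.add(r.x)
            edges.add(r.x + r.width)
        else:
            edges.add(r.y)
            edges.add(r.y + r.height)
    return sorted(edges)


def partitions(bounds: Sequence[float]) -> list[IntervalWindow]:
    """Turn sorted distinct edge coordinates into half-open interval windows.

    n bounds give n-1 windows tiling [min, max) exactly; an empty input
    gives no windows.
    """
    bounds = list(bounds)
    if any(b0 >= b1 for b0, b1 in zip(bounds, bounds[1:])):
        raise ContractError("bounds must be strictly increasing")
    return [IntervalWindow(b0, b1) for b0, b1 in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------


@dataclass
class _GridData:
    """Columnar overlap grid shared by the public contract objects."""

    xb: np.ndarray  # x boundary coordinates, len nx+1 (or 0)
    yb: np.ndarray
    label_grid: np.ndarray  # (nx, ny) int64; -1 = uncovered
    indptr: np.ndarray  # CSR over distinct labels
    members: np.ndarray  # participant indices, ascending within a label
    participants: list[str]  # lexicographically sorted ids

    @property
    def n_labels(self) -> int:
        return len(self.indptr) - 1

    def label_set(self, label: int) -> frozenset[str]:
        lo, hi = self.indptr[label], self.indptr[label + 1]
        return frozenset(self.participants[m] for m in self.members[lo:hi])


def _participant_keys(participants: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2x64-bit keys per participant id (identity-based, so
    results are invariant to input order)."""
    k1 = np.empty(len(participants), np.uint64)
    k2 = np.empty(len(participants), np.uint64)
    for i, p in enumerate(participants):
        digest = hashlib.blake2b(p.encode("utf-8"), digest_size=16).digest()
        a, b = struct.unpack("<QQ", digest)
        k1[i], k2[i] = a, b
    return k1, k2


def _build_grid(recordings: Sequence[PainRecording]) -> _GridData:
    xb = np.asarray(boundaries(recordings, "x"), dtype=float)
    yb = np.asarray(boundaries(recordings, "y"), dtype=float)
    participants = sorted({r.participant for r in recordings})
    if len(recordings) == 0:
        return _GridData(
            xb,
            yb,
            np.full((0, 0), -1, np.int64),
            np.zeros(1, np.int64),
            np.empty(0, np.int64),
            participants,
        )
    nx, ny = len(xb) - 1, len(yb) - 1
    pindex = {p: i for i, p in enumerate(participants)}

    # window index span of each recording (edges are exact members of xb/yb)
    rx0 = np.searchsorted(xb, [r.x for r in recordings])
    rx1 = np.searchsorted(xb, [r.x + r.width for r in recordings])
    ry0 = np.searchsorted(yb, [r.y for r in recordings])
    ry1 = np.searchsorted(yb, [r.y + r.height for r in recordings])
    rp = np.array([pindex[r.participant] for r in recordings])

    k1, k2 = _participant_keys(participants)
    count = np.zeros((nx, ny), np.int32)
    h1 = np.zeros((nx, ny), np.uint64)
    h2 = np.zeros((nx, ny), np.uint64)

    by_participant: dict[int, list[int]] = {}
    for i, p in enumerate(rp):
        by_participant.setdefault(int(p), []).append(i)
    for p, idxs in by_participant.items():
        if len(idxs) == 1:
            i = idxs[0]
            sl = np.s_[rx0[i] : rx1[i], ry0[i] : ry1[i]]
            count[sl] += 1
            h1[sl] += k1[p]
            h2[sl] += k2[p]
        else:
            # union of this participant's rectangles must count once
            bx0, bx1 = rx0[idxs].min(), rx1[idxs].max()
            by0, by1 = ry0[idxs].min(), ry1[idxs].max()
            mask = np.zeros((bx1 - bx0, by1 - by0), bool)
            for i in idxs:
                mask[rx0[i] - bx0 : rx1[i] - bx0, ry0[i] - by0 : ry1[i] - by0] = True
            sl = np.s_[bx0:bx1, by0:by1]
            count[sl] += mask
            h1[sl] += mask * k1[p]
            h2[sl] += mask * k2[p]

    # identical (count, keysum) <=> identical participant set
    covered = count > 0
    c = count[covered]
    a = h1[covered]
    b = h2[covered]
    order = np.lexsort((b, a, c))
    cs, as_, bs = c[order], a[order], b[order]
    new = np.empty(cs.size, bool)
    new[0] = True
    new[1:] = (cs[1:] != cs[:-1]) | (as_[1:] != as_[:-1]) | (bs[1:] != bs[:-1])
    inverse = np.empty(cs.size, np.int64)
    inverse[order] = np.cumsum(new) - 1
    label_counts = cs[new].astype(np.int64)  # distinct-participant count per label
    n_labels = label_counts.size
    label_grid = np.full((nx, ny), -1, np.int64)
    label_grid[covered] = inverse

    # recover the member set of each distinct label: for every rectangle,
    # pair the labels under its footprint with its participant, then sort
    # pairs so each label's members come out grouped and ascending.
    # Deduplication happens per rectangle (cheap, cache-resident) so the
    # global pass usually needs no compaction copy.
    n_p = len(participants)
    spans = (rx1 - rx0) * (ry1 - ry0)
    keys_buf = np.empty(int(spans.sum()), np.int64)  # tail never touched
    pos = 0
    for i in range(len(recordings)):
        sub = label_grid[rx0[i] : rx1[i], ry0[i] : ry1[i]].flatten()
        sub.sort()
        if sub.size > 1:
            m = np.empty(sub.size, bool)
            m[0] = True
            np.not_equal(sub[1:], sub[:-1], out=m[1:])
            sub = sub[m]
        sub *= n_p
        sub += rp[i]
        keys_buf[pos : pos + sub.size] = sub
        pos += sub.size
    keys = keys_buf[:pos]
    keys.sort()
    if keys.size > 1:
        keep = np.empty(keys.size, bool)
        keep[0] = True
        np.not_equal(keys[1:], keys[:-1], out=keep[1:])
        if int(np.count_nonzero(keep)) != keys.size:
            # only participants drawing several marks over one spot dup
            keys = keys[keep]
    # label l owns the key range [l*n_p, (l+1)*n_p)
    indptr = np.searchsorted(keys, np.arange(n_labels + 1, dtype=np.int64) * n_p)
    members = np.empty(keys.size, np.int32)
    chunk = 16_000_000
    for s in range(0, keys.size, chunk):
        members[s : s + chunk] = keys[s : s + chunk] % n_p
    if not np.array_equal(np.diff(indptr), label_counts):
        raise RuntimeError(
            "overlap-set key collision detected; results would be unreliable"
        )
    return _GridData(xb, yb, label_grid, indptr, members, participants)


class OverlapGrid(Mapping):
    """Mapping from (x-window index, y-window index) to the set of
    distinct participants covering that grid cell; uncovered cells are
    absent. Backed by the columnar grid used throughout the pipeline."""

    def __init__(self, data: _GridData):
        self._data = data
        self._set_cache: dict[int, frozenset[str]] = {}

    @property
    def xwindows(self) -> list[IntervalWindow]:
        return partitions(self._data.xb)

    @property
    def ywindows(self) -> list[IntervalWindow]:
        return partitions(self._data.yb)

    def _set_for(self, label: int) -> frozenset[str]:
        got = self._set_cache.get(label)
        if got is None:
            got = self._set_cache[label] = self._data.label_set(label)
        return got

    def __getitem__(self, cell: tuple[int, int]) -> frozenset[str]:
        ix, iy = cell
        grid = self._data.label_grid
        if not (0 <= ix < grid.shape[0] and 0 <= iy < grid.shape[1]):
            raise KeyError(cell)
        label = grid[ix, iy]
        if label < 0:
            raise KeyError(cell)
        return self._set_for(int(label))

    def __iter__(self) -> Iterator[tuple[int, int]]:
        ixs, iys = np.nonzero(self._data.label_grid >= 0)
        return iter(zip(ixs.tolist(), iys.tolist()))

    def __len__(self) -> int:
        return int((self._data.label_grid >= 0).sum())


def overlap_grid(
    recordings: Sequence[PainRecording],
    xwin: Sequence[IntervalWindow] | None = None,
    ywin: Sequence[IntervalWindow] | None = None,
) -> OverlapGrid:
    """Assign participant overlap sets to the cells of the partition grid.

    ``xwin``/``ywin`` may be passed to assert they match the partitions
    derived from ``recordings`` (they are fully determined by them);
    a mismatch is a contract error.
    """
    data = _build_grid(recordings)
    for windows, bounds, name in ((xwin, data.xb, "x"), (ywin, data.yb, "y")):
        if windows is not None:
            expected = partitions(bounds)
            if list(windows) != expected:
                raise ContractError(
                    f"{name}-windows do not match the recordings' partitions"
                )
    return OverlapGrid(data)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _merge_segments(
    label_grid: np.ndarray, layout: Layout
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-pass maximal merge of the label grid.

    Returns window-index extents (ix0, ix1, iy0, iy1) and the label of
    each merged rectangle.
    """
    # pass 1: maximal equal-label runs along the layout axis, per band
    if layout is Layout.HORIZONTAL:
        rows = label_grid.T  # band = y-window, run along x
    else:
        rows = label_grid  # band = x-window, run along y
    n_bands, run_len = rows.shape
    flat = np.ascontiguousarray(rows).ravel()
    if flat.size == 0:
        e = np.empty(0, np.int64)
        return e, e, e, e, e
    change = np.empty(flat.size, bool)
    change[0] = True
    np.not_equal(flat[1:], flat[:-1], out=change[1:])
    change[::run_len] = True
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], flat.size)
    labels = flat[starts]
    keep = labels >= 0
    starts, ends, labels = starts[keep], ends[keep], labels[keep]
    band = starts // run_len
    r0 = starts % run_len
    r1 = (ends - 1) % run_len + 1

    # pass 2: fuse same-label, same-extent segments adjacent across bands;
    # consecutive-run fusion reaches the fixpoint in one sweep.
    order = np.lexsort((band, r1, r0, labels))
    labels, r0, r1, band = labels[order], r0[order], r1[order], band[order]
    if labels.size:
        new = np.empty(labels.size, bool)
        new[0] = True
        new[1:] = ~(
            (labels[1:] == labels[:-1])
            & (r0[1:] == r0[:-1])
            & (r1[1:] == r1[:-1])
            & (band[1:] == band[:-1] + 1)
        )
        first = np.flatnonzero(new)
        last = np.append(first[1:], labels.size) - 1
        labels, r0, r1 = labels[first], r0[first], r1[first]
        band0, band1 = band[first], band[last] + 1
    else:
        band0, band1 = band, band

    if layout is Layout.HORIZONTAL:
        return r0, r1, band0, band1, labels
    return band0, band1, r0, r1, labels


def merge_cells(
    grid: OverlapGrid, layout: Layout | str = Layout.HORIZONTAL,
    total_drawings: int | None = None,
) -> list[OutputRect]:
    """Merge grid cells into maximal disjoint rectangles with overlap sets.

    Proportions are computed against ``total_drawings`` when given,
    otherwise against the number of distinct participants in the grid.
    """
    layout = Layout(layout)
    data = grid._data
    denom = total_drawings if total_drawings is not None else max(len(data.participants), 1)
    ix0, ix1, iy0, iy1, labels = _merge_segments(data.label_grid, layout)
    sizes = np.diff(data.indptr)
    rects = []
    for a, b, c, d, lab in zip(ix0, ix1, iy0, iy1, labels):
        rects.append(
            OutputRect(
                float(data.xb[a]),
                float(data.yb[c]),
                float(data.xb[b] - data.xb[a]),
                float(data.yb[d] - data.yb[c]),
                grid._set_for(int(lab)),
                int(sizes[lab]),
                float(sizes[lab] / denom),
            )
        )
    rects.sort(key=lambda r: (r.y, r.x))
    return rects


# ---------------------------------------------------------------------------
# end-to-end computation and post-processing
# ---------------------------------------------------------------------------


def compute_overlap(
    ds: DrawingSet,
    layout: Layout | str = Layout.HORIZONTAL,
    denominator: Literal["total", "participants"] = "total",
) -> FrequencyMap:
    """Run the full pipeline on one region's drawing set.

    Chains edge decomposition, partitioning, overlap-set grid labelling
    and two-pass merging, then annotates every output rectangle with its
    overlap frequency |o| and proportion. The proportion denominator is
    the total drawing count T (including empty drawings) by default, or
    |P| (participants with a drawing) with ``denominator="participants"``.
    """
    layout = Layout(layout)
    if denominator not in ("total", "participants"):
        raise ContractError(f"unknown denominator choice {denominator!r}")
    data = _build_grid(ds.recordings)
    denom = (
        ds.total_drawings
        if denominator == "total"
        else max(len(ds.participants), 1)
    )
    if len(ds.recordings) == 0:
        fm = FrequencyMap.empty(ds.region, ds.total_drawings, layout)
        fm.denominator = denom
        return fm
    ix0, ix1, iy0, iy1, labels = _merge_segments(data.label_grid, layout)
    x = data.xb[ix0]
    y = data.yb[iy0]
    w = data.xb[ix1] - x
    h = data.yb[iy1] - y
    order = np.lexsort((x, y))
    return FrequencyMap(
        ds.region,
        ds.total_drawings,
        layout,
        x[order],
        y[order],
        w[order],
        h[order],
        labels[order],
        data.indptr,
        data.members,
        data.participants,
        denominator=denom,
    )


def compute_overlap_by_region(
    drawing_sets: Sequence[DrawingSet],
    layout: Layout | str = Layout.HORIZONTAL,
    denominator: Literal["total", "participants"] = "total",
) -> list[FrequencyMap]:
    """Process several regions independently, in alphabetical region order."""
    return [
        compute_overlap(ds, layout, denominator)
        for ds in sorted(drawing_sets, key=lambda d: d.region)
    ]


def filter_map(
    fm: FrequencyMap,
    min_freq: int = 1,
    max_freq: int | None = None,
    min_width: float = 0.0,
    min_height: float = 0.0,
) -> FrequencyMap:
    """Keep rectangles with min_freq <= frequency <= max_freq (inclusive)
    and width/height at or above the thresholds. Proportions are left
    untouched (the denominator stays T)."""
    if max_freq is None:
        max_freq = fm.max_frequency if fm.max_frequency is not None else min_freq
    if min_freq > max_freq:
        raise ContractError(f"inverted frequency range [{min_freq}, {max_freq}]")
    if min_width < 0 or min_height < 0:
        raise ContractError("size thresholds must be >= 0")
    freq = fm.frequencies
    keep = (
        (freq >= min_freq)
        & (freq <= max_freq)
        & (fm.width >= min_width)
        & (fm.height >= min_height)
    )
    return fm._take(np.flatnonzero(keep))


def apply_null_mask(fm: FrequencyMap, null_id: str) -> FrequencyMap:
    """Remove the synthetic template-filling *null* drawing from a map.

    The null drawing tiles the whole template; after running the overlap
    computation on real + null drawings together, only rectangles shared
    by the null drawing and at least one real drawing lie within the
    template, so rectangles covered by the null drawing alone are
    dropped, the null participant is removed from every overlap set,
    frequencies drop by one and proportions are recomputed with the null
    drawing excluded from the denominator.
    """
    try:
        pidx = fm.participants.index(null_id)
    except ValueError:
        raise MaskError(f"null drawing {null_id!r} not present in the map") from None
    n_sets = len(fm.set_indptr) - 1
    set_ids = np.repeat(np.arange(n_sets), fm.set_sizes)
    has_null = np.zeros(n_sets, bool)
    has_null[set_ids[fm.set_members == pidx]] = True
    if not has_null.any():
        raise MaskError(f"null drawing {null_id!r} overlaps no output rectangle")

    keep_set = has_null & (fm.set_sizes >= 2)
    keep_rect = keep_set[fm.set_of_rect]
    # rebuild the set table without the null participant
    keep_member = (fm.set_members != pidx) & keep_set[set_ids]
    new_members = fm.set_members[keep_member]
    counts = np.bincount(set_ids[keep_member], minlength=n_sets)
    new_id = np.cumsum(keep_set) - 1
    indptr = np.zeros(int(keep_set.sum()) + 1, np.int64)
    np.cumsum(counts[keep_set], out=indptr[1:])
    if fm.denominator < 2:
        raise MaskError("masking would leave no real drawings in the denominator")
    masked = FrequencyMap(
        fm.region,
        fm.total_drawings - 1,
        fm.layout,
        fm.x[keep_rect],
        fm.y[keep_rect],
        fm.width[keep_rect],
        fm.height[keep_rect],
        new_id[fm.set_of_rect[keep_rect]],
        indptr,
        new_members,
        fm.participants,
        denominator=fm.denominator - 1,
    )
    return masked
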