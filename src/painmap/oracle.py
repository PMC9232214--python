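"""Brute-force pixel rasterization of pain recordings.

This is the independent cross-check for the overlap algorithm: on
integer-coordinate inputs, every unit pixel is assigned the set of
distinct participants whose footprint contains it, by direct per-pixel
filling rather than coordinate compression. Intended for validation on
small instances, not for production maps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import ContractError, PainRecording

__all__ = ["PixelOracle", "rasterize_oracle"]


class PixelOracle:
    """Per-pixel participant sets over an integer bounding box.

    Pixels are unit cells [px, px+1) x [py, py+1) in template
    coordinates, stored as bitmasks over at most 64 participants.
    """

    def __init__(
        self,
        x0: int,
        y0: int,
        bits: np.ndarray,
        participants: list[str],
    ) -> None:
        self.x0 = x0
        self.y0 = y0
        self.bits = bits  # (width, height) uint64 bitmask grid
        self.participants = participants  # lexicographically sorted

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    def bitmask_of(self, ids: frozenset[str] | set[str]) -> int:
        mask = 0
        for p in ids:
            mask |= 1 << self.participants.index(p)
        return mask

    def set_of_bits(self, mask: int) -> frozenset[str]:
        return frozenset(
            p for i, p in enumerate(self.participants) if mask >> i & 1
        )

    def set_at(self, px: int, py: int) -> frozenset[str]:
        """Participant set covering pixel [px, px+1) x [py, py+1)."""
        ix, iy = px - self.x0, py - self.y0
        if not (0 <= ix < self.bits.shape[0] and 0 <= iy < self.bits.shape[1]):
            return frozenset()
        return self.set_of_bits(int(self.bits[ix, iy]))

    def area_by_set(self) -> dict[frozenset[str], int]:
        """Pixel count per distinct nonempty participant set."""
        values, counts = np.unique(self.bits, return_counts=True)
        return {
            self.set_of_bits(int(v)): int(c)
            for v, c in zip(values, counts)
            if v != 0
        }

    def covered_area(self) -> int:
        return int((self.bits != 0).sum())


def rasterize_oracle(
    recordings: Sequence[PainRecording],
    bbox: tuple[int, int, int, int] | None = None,
    resolution: int = 1,
) -> PixelOracle:
    """Rasterize recordings onto a unit-pixel grid of participant sets.

    Parameters
    ----------
    recordings
        Integer-coordinate recordings (after division by ``resolution``).
    bbox
        (x0, y0, x1, y1); defaults to the recordings' bounding box.
    resolution
        Unit-cell edge length; all coordinates must be multiples of it.
    """
    if resolution < 1:
        raise ContractError("resolution must be a positive integer")
    scaled = []
    for r in recordings:
        coords = (r.x, r.y, r.width, r.height)
        q = [c / resolution for c in coords]
        if any(v != int(v) for v in q):
            raise ContractError(
                f"coordinates {coords} are not multiples of resolution={resolution}"
            )
        scaled.append((r.participant, *(int(v) for v in q)))

    participants = sorted({p for p, *_ in scaled})
    if len(participants) > 64:
        raise ContractError("pixel oracle supports at most 64 participants")
    pindex = {p: i for i, p in enumerate(participants)}

    if bbox is None:
        if scaled:
            x0 = min(s[1] for s in scaled)
            y0 = min(s[2] for s in scaled)
            x1 = max(s[1] + s[3] for s in scaled)
            y1 = max(s[2] + s[4] for s in scaled)
        else:
            x0 = y0 = x1 = y1 = 0
    else:
        x0, y0, x1, y1 = (int(v / resolution) for v in bbox)
    bits = np.zeros((max(x1 - x0, 0), max(y1 - y0, 0)), np.uint64)
    for p, rx, ry, rw, rh in scaled:
        bit = np.uint64(1 << pindex[p])
        sx0, sx1 = max(rx - x0, 0), min(rx + rw - x0, bits.shape[0])
        sy0, sy1 = max(ry - y0, 0), min(ry + rh - y0, bits.shape[1])
        if sx0 < sx1 and sy0 < sy1:
            bits[sx0:sx1, sy0:sy1] |= bit
    return PixelOracle(x0, y0, bits, participants)
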