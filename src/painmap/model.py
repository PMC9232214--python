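"""Domain types for grid-free pain-drawing quantification.

A participant draws on a 2D body template with a square pencil tip; every
click deposits an axis-aligned square. The analysis decomposes all
participants' overlapping rectangles into disjoint ("nonoverlapping")
rectangles, each carrying the set of participants whose drawings cover it.

Conventions used throughout the package:

* coordinates are template pixels, *y grows downward* (SVG convention);
* a rectangle with top-left corner (x, y) and size (w, h) occupies the
  half-open box [x, x+w) x [y, y+h), so abutting rectangles neither
  overlap nor leave a gap;
* coordinates are reals and are never rounded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "PainMapError",
    "ContractError",
    "InvalidRecordingError",
    "SchemaError",
    "DrawingParseError",
    "MaskError",
    "Visibility",
    "Layout",
    "PainRecording",
    "DrawingSet",
    "IntervalWindow",
    "OutputRect",
    "FrequencyMap",
]


class PainMapError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(PainMapError, ValueError):
    """An operation was called with arguments violating its precondition."""


class InvalidRecordingError(ContractError):
    """A pain recording has non-positive width or height."""


class SchemaError(PainMapError, ValueError):
    """An input table or SVG element is missing required fields."""


class DrawingParseError(PainMapError):
    """An SVG drawing document could not be parsed."""


class MaskError(PainMapError, ValueError):
    """Null-drawing masking was requested but the null drawing is absent."""


class Visibility(str, enum.Enum):
    """Visibility status of a recording; ``hidden`` means erased."""

    VISIBLE = "visible"
    HIDDEN = "hidden"


class Layout(str, enum.Enum):
    """Merge direction preference: horizontal gives wider output
    rectangles, vertical gives longer (taller) ones."""

    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


@dataclass(frozen=True)
class PainRecording:
    """One pencil mark: a square (in practice) rectangle on the template.

    Parameters
    ----------
    participant
        Identifier of the drawing this mark belongs to.
    x, y
        Template-pixel coordinates of the top-left corner.
    width, height
        Strictly positive extents; the footprint is the half-open box
        ``[x, x+width) x [y, y+height)``.
    region
        Body-template region label (e.g. ``"front"``, ``"back"``).
    visibility
        ``visible`` or ``hidden`` (= erased by the participant).
    order
        Insertion index within the source document; used to resolve
        draw-then-erase sequences on identical geometry.
    """

    participant: str
    x: float
    y: float
    width: float
    height: float
    region: str = "front"
    visibility: Visibility = Visibility.VISIBLE
    order: int = 0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise InvalidRecordingError(
                f"recording for {self.participant!r} at ({self.x}, {self.y}) has "
                f"non-positive size {self.width} x {self.height}"
            )
        if isinstance(self.visibility, str) and not isinstance(
            self.visibility, Visibility
        ):
            object.__setattr__(self, "visibility", Visibility(self.visibility))

    @property
    def is_visible(self) -> bool:
        return self.visibility is Visibility.VISIBLE

    def geometry(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.width, self.height)


@dataclass
class DrawingSet:
    """All recordings for one region plus the drawing-count denominator.

    ``total_drawings`` (T) counts every submitted drawing, *including
    empty ones* (participants who reported no pain); it is the default
    denominator for overlap proportions. ``participants`` (P) is the set
    of participants with at least one visible recording, so |P| <= T.
    """

    recordings: list[PainRecording]
    total_drawings: int
    participants: frozenset[str] = field(default=frozenset())
    region: str = "front"

    def __post_init__(self) -> None:
        if not self.participants:
            self.participants = frozenset(r.participant for r in self.recordings)
        if self.total_drawings < 1:
            raise ContractError("total_drawings must be >= 1")
        if len(self.participants) > self.total_drawings:
            raise ContractError(
                f"{len(self.participants)} distinct participants exceed "
                f"total_drawings={self.total_drawings}"
            )
        stray = {r.participant for r in self.recordings} - self.participants
        if stray:
            raise ContractError(f"recordings from unknown participants: {sorted(stray)}")

    @classmethod
    def from_recordings(
        cls,
        recordings: Iterable[PainRecording],
        total_drawings: int | None = None,
        region: str | None = None,
    ) -> "DrawingSet":
        recs = list(recordings)
        participants = frozenset(r.participant for r in recs)
        if total_drawings is None:
            total_drawings = max(len(participants), 1)
        if region is None:
            region = recs[0].region if recs else "front"
        return cls(recs, total_drawings, participants, region)


@dataclass(frozen=True, order=True)
class IntervalWindow:
    """A half-open coordinate partition ``[start, end)`` along one axis."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ContractError(f"degenerate window [{self.start}, {self.end})")

    @property
    def size(self) -> float:
        return self.end - self.start

    def __contains__(self, value: float) -> bool:
        return self.start <= value < self.end


@dataclass(frozen=True)
class OutputRect:
    """A disjoint output rectangle: one unique template location.

    ``overlap`` is the set of distinct participants whose drawings cover
    the whole rectangle; ``overlap_frequency`` = |overlap| and
    ``overlap_proportion`` = |overlap| / T (T includes empty drawings).
    """

    x: float
    y: float
    width: float
    height: float
    overlap: frozenset[str]
    overlap_frequency: int
    overlap_proportion: float

    def __post_init__(self) -> None:
        if not self.overlap:
            raise ContractError("output rectangle with empty overlap set")
        if self.overlap_frequency != len(self.overlap):
            raise ContractError("overlap_frequency != |overlap|")
        if not 0 < self.overlap_proportion <= 1:
            raise ContractError("overlap_proportion outside (0, 1]")

    @property
    def area(self) -> float:
        return self.width * self.height

    def footprint(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the half-open box."""
        return (self.x, self.y, self.x + self.width, self.y + self.height)


class FrequencyMap:
    """Per-region collection of disjoint output rectangles.

    Stored column-wise (numpy arrays plus a CSR table of distinct
    overlap sets) so that maps with hundreds of thousands of rectangles
    stay cheap; :attr:`rects` materialises :class:`OutputRect` objects
    on demand. Rectangles are ordered by (y, x).
    """

    def __init__(
        self,
        region: str,
        total_drawings: int,
        layout: Layout,
        x: np.ndarray,
        y: np.ndarray,
        width: np.ndarray,
        height: np.ndarray,
        set_of_rect: np.ndarray,
        set_indptr: np.ndarray,
        set_members: np.ndarray,
        participants: Sequence[str],
        denominator: int | None = None,
    ) -> None:
        self.region = region
        self.total_drawings = int(total_drawings)
        self.layout = Layout(layout)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.width = np.asarray(width, dtype=float)
        self.height = np.asarray(height, dtype=float)
        self.set_of_rect = np.asarray(set_of_rect, dtype=np.int64)
        self.set_indptr = np.asarray(set_indptr, dtype=np.int64)
        # left in its given integer dtype (int32 from the core pipeline)
        self.set_members = np.asarray(set_members)
        #: participant ids, sorted lexicographically; ``set_members``
        #: holds indices into this list, ascending within each set.
        self.participants = list(participants)
        #: proportion denominator; defaults to total_drawings (T) and is
        #: reduced by one after null-drawing masking.
        self.denominator = int(total_drawings if denominator is None else denominator)
        if self.denominator < 1:
            raise ContractError("proportion denominator must be >= 1")

    # -- construction ---------------------------------------------------

    @classmethod
    def empty(
        cls, region: str, total_drawings: int, layout: Layout = Layout.HORIZONTAL
    ) -> "FrequencyMap":
        z = np.empty(0)
        zi = np.empty(0, dtype=np.int64)
        return cls(region, total_drawings, layout, z, z, z, z, zi, np.zeros(1, np.int64), zi, [])

    @classmethod
    def from_rects(
        cls,
        rects: Iterable[OutputRect],
        region: str,
        total_drawings: int,
        layout: Layout = Layout.HORIZONTAL,
        denominator: int | None = None,
    ) -> "FrequencyMap":
        rects = list(rects)
        if not rects:
            fm = cls.empty(region, total_drawings, layout)
            if denominator is not None:
                fm.denominator = int(denominator)
            return fm
        participants = sorted(set().union(*(r.overlap for r in rects)))
        pindex = {p: i for i, p in enumerate(participants)}
        distinct: dict[frozenset, int] = {}
        set_of_rect = np.empty(len(rects), np.int64)
        for i, r in enumerate(rects):
            set_of_rect[i] = distinct.setdefault(r.overlap, len(distinct))
        indptr = [0]
        members: list[int] = []
        for s in distinct:
            members.extend(sorted(pindex[p] for p in s))
            indptr.append(len(members))
        fm = cls(
            region,
            total_drawings,
            layout,
            np.array([r.x for r in rects]),
            np.array([r.y for r in rects]),
            np.array([r.width for r in rects]),
            np.array([r.height for r in rects]),
            set_of_rect,
            np.array(indptr, np.int64),
            np.array(members, np.int64),
            participants,
            denominator=denominator,
        )
        order = np.lexsort((fm.x, fm.y))
        return fm._take(order)

    # -- derived columns ------------------------------------------------

    def __len__(self) -> int:
        return self.x.size

    @property
    def set_sizes(self) -> np.ndarray:
        return np.diff(self.set_indptr)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-rectangle overlap frequency |o|."""
        if len(self) == 0:
            return np.empty(0, np.int64)
        return self.set_sizes[self.set_of_rect]

    @property
    def proportions(self) -> np.ndarray:
        return self.frequencies / self.denominator

    @property
    def areas(self) -> np.ndarray:
        return self.width * self.height

    @property
    def max_frequency(self) -> int | None:
        """Largest overlap frequency, or None for an empty map."""
        if len(self) == 0:
            return None
        return int(self.frequencies.max())

    def overlap_set(self, set_id: int) -> frozenset[str]:
        lo, hi = self.set_indptr[set_id], self.set_indptr[set_id + 1]
        return frozenset(self.participants[m] for m in self.set_members[lo:hi])

    @cached_property
    def rects(self) -> list[OutputRect]:
        """Materialised :class:`OutputRect` list (sorted by y then x)."""
        sets = [self.overlap_set(s) for s in range(len(self.set_indptr) - 1)]
        freq = self.frequencies
        prop = self.proportions
        return [
            OutputRect(
                float(self.x[i]),
                float(self.y[i]),
                float(self.width[i]),
                float(self.height[i]),
                sets[self.set_of_rect[i]],
                int(freq[i]),
                float(prop[i]),
            )
            for i in range(len(self))
        ]

    def __iter__(self) -> Iterator[OutputRect]:
        return iter(self.rects)

    def _take(self, index: np.ndarray) -> "FrequencyMap":
        """Row subset/permutation sharing the overlap-set table."""
        return FrequencyMap(
            self.region,
            self.total_drawings,
            self.layout,
            self.x[index],
            self.y[index],
            self.width[index],
            self.height[index],
            self.set_of_rect[index],
            self.set_indptr,
            self.set_members,
            self.participants,
            denominator=self.denominator,
        )

    # -- export ---------------------------------------------------------

    def overlap_strings(self, sep: str = ";") -> list[str]:
        """Per-rectangle overlap set serialised as sorted ids joined by
        ``sep`` (ids are lexicographically sorted by construction)."""
        per_set = [
            sep.join(self.participants[m] for m in self.set_members[lo:hi])
            for lo, hi in zip(self.set_indptr[:-1], self.set_indptr[1:])
        ]
        return [per_set[s] for s in self.set_of_rect]

    def to_frame(self, include_region: bool = False):
        """Output table: x, y, width, height, area, overlap,
        overlap_frequency, overlap_proportion[, region]."""
        import pandas as pd

        frame = pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "width": self.width,
                "height": self.height,
                "area": self.areas,
                "overlap": self.overlap_strings(),
                "overlap_frequency": self.frequencies,
                "overlap_proportion": self.proportions,
            }
        )
        if include_region:
            frame["region"] = self.region
        return frame

    def area_by_overlap_set(self) -> dict[frozenset[str], float]:
        """Total area per distinct overlap set (layout-invariant)."""
        n_sets = len(self.set_indptr) - 1
        totals = np.zeros(n_sets)
        np.add.at(totals, self.set_of_rect, self.areas)
        return {
            self.overlap_set(s): float(totals[s])
            for s in range(n_sets)
            if totals[s] > 0
        }
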