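"""Reading drawings and tables: SVG extraction, eraser semantics, CSV schemas.

A drawing is captured as one SVG document per participant; every pencil
mark is a ``<rect>`` element whose width and height are equal (the
pencil tip is square). Non-square rects belong to the template and are
skipped. An element's ``visibility`` attribute records erasure
(``hidden`` means erased); ``data-region`` carries the body region.

The CSV input schema is ``participant,x,y,width,height,region`` with an
optional ``visibility`` column; output tables follow the schema of
:meth:`painmap.model.FrequencyMap.to_frame`. Leading ``# key=value``
comment lines carry pipeline metadata (e.g. the total drawing count
including empty submissions) across chained commands.
"""

from __future__ import annotations

import dataclasses
import io
import os
import sys
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from lxml import etree

from .model import (
    DrawingParseError,
    DrawingSet,
    FrequencyMap,
    PainRecording,
    SchemaError,
    Visibility,
)

__all__ = [
    "parse_svg_drawing",
    "deduplicate",
    "load_drawing_set",
    "read_recordings_csv",
    "write_recordings_csv",
    "write_overlap_csv",
    "read_overlap_csv",
]

REQUIRED_COLUMNS = ("participant", "x", "y", "width", "height", "region")


def parse_svg_drawing(
    source: str | os.PathLike | bytes | IO,
    participant: str | None = None,
    default_region: str = "front",
) -> list[PainRecording]:
    """Extract pain recordings from one participant's SVG document.

    Every ``<rect>`` with equal width and height is a recording; other
    rects (template geometry) are skipped. The participant id defaults
    to the file name stem. Insertion (document) order is preserved in
    the ``order`` field; hidden recordings are kept here and resolved by
    :func:`deduplicate`.
    """
    if participant is None:
        if isinstance(source, (str, os.PathLike)) and not (
            isinstance(source, str) and source.lstrip().startswith("<")
        ):
            participant = Path(source).stem
        else:
            raise SchemaError("participant id required when not parsing from a file")
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            root = etree.parse(str(source)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise DrawingParseError(f"cannot parse SVG drawing: {exc}") from exc

    recordings: list[PainRecording] = []
    order = 0
    for el in root.iter("{*}rect"):
        w, h = el.get("width"), el.get("height")
        if w is None or h is None:
            continue  # not a pain recording
        try:
            w_val, h_val = float(w), float(h)
        except ValueError as exc:
            raise SchemaError(f"non-numeric rect size {w!r} x {h!r}") from exc
        if w_val != h_val:
            continue  # template geometry: the pencil tip is square
        x, y = el.get("x"), el.get("y")
        if x is None or y is None:
            raise SchemaError(
                f"square rect ({w} x {h}) in drawing {participant!r} lacks x/y"
            )
        visibility = (
            Visibility.HIDDEN
            if el.get("visibility", "visible").strip().lower() == "hidden"
            else Visibility.VISIBLE
        )
        recordings.append(
            PainRecording(
                participant=participant,
                x=float(x),
                y=float(y),
                width=w_val,
                height=h_val,
                region=el.get("data-region", default_region),
                visibility=visibility,
                order=order,
            )
        )
        order += 1
    return recordings


def deduplicate(recordings: Sequence[PainRecording]) -> list[PainRecording]:
    """Resolve duplicate and erased recordings.

    Recordings with identical (participant, x, y, width, height) —
    complete overlay, exact equality — collapse to a single instance
    whose visibility is that of the *last* occurrence; if that status is
    hidden (erased) the recording is dropped. The result contains only
    visible, unique recordings, in first-occurrence order.
    """
    first: dict[tuple, PainRecording] = {}
    last_status: dict[tuple, Visibility] = {}
    for r in sorted(recordings, key=lambda r: r.order):
        key = (r.participant, r.region, r.x, r.y, r.width, r.height)
        first.setdefault(key, r)
        last_status[key] = r.visibility
    survivors = [
        dataclasses.replace(first[key], visibility=status)
        for key, status in last_status.items()
        if status is Visibility.VISIBLE
    ]
    survivors.sort(key=lambda r: r.order)
    return survivors


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------


def _read_metadata(buf: IO[str]) -> dict[str, str]:
    """Consume leading '# key=value' comment lines."""
    meta: dict[str, str] = {}
    while True:
        pos = buf.tell()
        line = buf.readline()
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
        else:
            buf.seek(pos)
            return meta


def _open_text(path_or_buf, mode: str = "r"):
    if path_or_buf == "-":
        return (sys.stdin if "r" in mode else sys.stdout), False
    if isinstance(path_or_buf, (str, os.PathLike)):
        return open(path_or_buf, mode, encoding="utf-8", newline=""), True
    return path_or_buf, False


def read_recordings_csv(
    path_or_buf,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an input recordings table plus its '#' metadata header.

    Requires columns participant,x,y,width,height,region; visibility is
    optional (default visible).
    """
    buf, close = _open_text(path_or_buf)
    try:
        if buf is sys.stdin:
            buf = io.StringIO(buf.read())
        meta = _read_metadata(buf)
        frame = pd.read_csv(buf, dtype={"participant": str, "region": str})
    finally:
        if close:
            buf.close()
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"input CSV lacks required columns: {missing}")
    if "visibility" not in frame.columns:
        frame["visibility"] = Visibility.VISIBLE.value
    return frame, meta


def recordings_from_frame(frame: pd.DataFrame) -> list[PainRecording]:
    recs = []
    for order, row in enumerate(frame.itertuples(index=False)):
        recs.append(
            PainRecording(
                participant=str(row.participant),
                x=float(row.x),
                y=float(row.y),
                width=float(row.width),
                height=float(row.height),
                region=str(row.region),
                visibility=Visibility(str(getattr(row, "visibility", "visible"))),
                order=order,
            )
        )
    return recs


def recordings_to_frame(recordings: Iterable[PainRecording]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant": r.participant,
                "x": r.x,
                "y": r.y,
                "width": r.width,
                "height": r.height,
                "region": r.region,
                "visibility": r.visibility.value,
            }
            for r in recordings
        ],
        columns=[*REQUIRED_COLUMNS, "visibility"],
    )


def write_recordings_csv(
    recordings: Iterable[PainRecording] | pd.DataFrame,
    path_or_buf,
    metadata: dict | None = None,
) -> None:
    frame = (
        recordings
        if isinstance(recordings, pd.DataFrame)
        else recordings_to_frame(recordings)
    )
    buf, close = _open_text(path_or_buf, "w")
    try:
        for key, value in (metadata or {}).items():
            buf.write(f"# {key}={value}\n")
        frame.to_csv(buf, index=False)
    finally:
        if close:
            buf.close()


def write_overlap_csv(
    maps: FrequencyMap | Sequence[FrequencyMap],
    path_or_buf,
    include_region: bool = True,
    metadata: dict | None = None,
) -> None:
    """Write output rectangles; proportions printed with 4 decimals."""
    if isinstance(maps, FrequencyMap):
        maps = [maps]
    frames = [fm.to_frame(include_region=include_region) for fm in maps]
    frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if "overlap_proportion" in frame.columns:
        frame = frame.assign(
            overlap_proportion=frame["overlap_proportion"].map("{:.4f}".format)
        )
    buf, close = _open_text(path_or_buf, "w")
    try:
        for key, value in (metadata or {}).items():
            buf.write(f"# {key}={value}\n")
        frame.to_csv(buf, index=False)
    finally:
        if close:
            buf.close()


def read_overlap_csv(path_or_buf) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an output-rectangle table plus its '#' metadata header."""
    buf, close = _open_text(path_or_buf)
    try:
        if buf is sys.stdin:
            buf = io.StringIO(buf.read())
        meta = _read_metadata(buf)
        frame = pd.read_csv(buf)
    finally:
        if close:
            buf.close()
    needed = {"x", "y", "width", "height", "overlap_frequency", "overlap_proportion"}
    missing = needed - set(frame.columns)
    if missing:
        raise SchemaError(f"overlap CSV lacks required columns: {sorted(missing)}")
    return frame, meta


# ---------------------------------------------------------------------------
# drawing-set assembly
# ---------------------------------------------------------------------------


def load_drawing_set(
    source,
    region_filter: str | None = None,
    include_empty: bool = True,
    default_region: str = "front",
    total_drawings: int | None = None,
    known_regions: Iterable[str] | None = None,
) -> DrawingSet:
    """Assemble a :class:`DrawingSet` from SVG files, a CSV, or a frame.

    ``source`` may be a directory of ``*.svg`` files (one per
    participant, id = file stem), a list of SVG paths, a CSV path/stream
    in the input schema, or a pandas DataFrame. Recordings are
    deduplicated with eraser semantics, then optionally restricted to
    ``region_filter``. Empty drawings (no visible recordings) count
    toward the total drawing count T iff ``include_empty``;
    ``total_drawings`` overrides the inferred T (e.g. when empty
    submissions are not representable in a CSV).
    """
    svg_paths: list[Path] | None = None
    if isinstance(source, (str, os.PathLike)) and source != "-":
        p = Path(source)
        if p.is_dir():
            svg_paths = sorted(p.glob("*.svg"))
        elif p.suffix.lower() == ".svg":
            svg_paths = [p]
    elif isinstance(source, (list, tuple)) and all(
        isinstance(s, (str, os.PathLike)) for s in source
    ):
        svg_paths = [Path(s) for s in source]

    if svg_paths is not None:
        raw: list[PainRecording] = []
        for path in svg_paths:
            raw.extend(parse_svg_drawing(path, default_region=default_region))
        n_drawings = len(svg_paths)
        recs = deduplicate(raw)
    else:
        if isinstance(source, pd.DataFrame):
            frame, meta = source, {}
        else:
            frame, meta = read_recordings_csv(source)
        recs = deduplicate(recordings_from_frame(frame))
        n_drawings = frame["participant"].nunique()
        if total_drawings is None and "total_drawings" in meta:
            total_drawings = int(meta["total_drawings"])

    if known_regions is not None:
        known = set(known_regions)
        unknown = {r.region for r in recs} - known
        if unknown:
            raise SchemaError(f"unknown region labels: {sorted(unknown)}")
    if region_filter is not None:
        recs = [r for r in recs if r.region == region_filter]

    if total_drawings is None:
        if include_empty:
            total_drawings = n_drawings
        else:
            total_drawings = len({r.participant for r in recs})
    total_drawings = max(int(total_drawings), 1)
    region = region_filter if region_filter is not None else (
        recs[0].region if recs else default_region
    )
    return DrawingSet.from_recordings(recs, total_drawings, region)


def split_by_region(
    source,
    include_empty: bool = True,
    default_region: str = "front",
    total_drawings: int | None = None,
) -> list[DrawingSet]:
    """One DrawingSet per region present in the input, alphabetical.
    Every region's T counts all drawings (a participant who drew only
    elsewhere contributes an empty drawing to this region)."""
    full = load_drawing_set(
        source,
        include_empty=include_empty,
        default_region=default_region,
        total_drawings=total_drawings,
    )
    regions = sorted({r.region for r in full.recordings})
    out = []
    for region in regions:
        recs = [r for r in full.recordings if r.region == region]
        out.append(DrawingSet.from_recordings(recs, full.total_drawings, region))
    return out
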