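"""Synthetic drawing workloads and deterministic geometry fixtures.

Two workloads emulate increasing load on the overlap algorithm, both on
a 1000x1000 plane with origin (0, 0) and one region ("xy-plane"):

* **single-click** — every participant contributes exactly one
  rectangle (one mouse click); dataset sizes grow in steps of 10,000
  rectangles.
* **participants** — every participant contributes 100 rectangles (a
  typical freehand drawing); dataset sizes grow in steps of 100
  participants.

Rectangle origins are sampled *without* replacement from the plane's
integer ordered pairs; widths and heights are sampled independently
*with* replacement from 10, 20, ..., 100. Rectangles may extend past
the plane's right/bottom edge; they are recorded as drawn, not clipped.

The named fixtures are small deterministic geometries (nested squares,
a three-way overlap, a worked two-square pair) exercising every code
path without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ContractError, DrawingSet, PainRecording

__all__ = [
    "SimulationConfig",
    "simulate_single_click",
    "simulate_participants",
    "fixtures",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation plane and pencil-size settings."""

    plane_width: int = 1000
    plane_height: int = 1000
    dim_start: int = 10
    dim_stop: int = 100
    dim_step: int = 10
    region: str = "xy-plane"

    @property
    def dimensions(self) -> np.ndarray:
        """Allowed pencil sizes: 10, 20, ..., 100 by default."""
        return np.arange(self.dim_start, self.dim_stop + 1, self.dim_step)

    @property
    def n_origins(self) -> int:
        return self.plane_width * self.plane_height


DEFAULT_CONFIG = SimulationConfig()


def _sample_origins(
    rng: np.random.Generator, n: int, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    if n > cfg.n_origins:
        raise ContractError(
            f"cannot draw {n} distinct origins from a "
            f"{cfg.plane_width}x{cfg.plane_height} plane"
        )
    flat = rng.choice(cfg.n_origins, size=n, replace=False)
    return flat % cfg.plane_width, flat // cfg.plane_width


def _assemble(
    participant: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    dims: np.ndarray,
    cfg: SimulationConfig,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": participant,
            "x": x,
            "y": y,
            "width": dims[:, 0],
            "height": dims[:, 1],
            "region": cfg.region,
        }
    )


def simulate_single_click(
    n_rects: int,
    cfg: SimulationConfig = DEFAULT_CONFIG,
    seed: int | None = None,
) -> pd.DataFrame:
    """Single-click workload: ``n_rects`` rectangles, one distinct
    participant each, distinct origins, sizes from the pencil sequence."""
    rng = np.random.default_rng(seed)
    x, y = _sample_origins(rng, n_rects, cfg)
    dims = rng.choice(cfg.dimensions, size=(n_rects, 2), replace=True)
    width = len(str(max(n_rects, 1)))
    participant = np.array([f"P{i + 1:0{width}d}" for i in range(n_rects)])
    return _assemble(participant, x, y, dims, cfg)


def simulate_participants(
    n_participants: int,
    clicks: int = 100,
    cfg: SimulationConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    origins_without_replacement: str = "dataset",
) -> pd.DataFrame:
    """Participant-drawing workload: ``clicks`` rectangles per participant.

    ``origins_without_replacement`` chooses the scope of the
    without-replacement origin sampling: ``"dataset"`` (default; all
    origins in the dataset distinct) or ``"participant"`` (distinct
    within each participant's drawing only).
    """
    if origins_without_replacement not in ("dataset", "participant"):
        raise ContractError(
            f"unknown origin sampling scope {origins_without_replacement!r}"
        )
    rng = np.random.default_rng(seed)
    n = n_participants * clicks
    if origins_without_replacement == "dataset":
        x, y = _sample_origins(rng, n, cfg)
    else:
        xs, ys = [], []
        for _ in range(n_participants):
            px, py = _sample_origins(rng, clicks, cfg)
            xs.append(px)
            ys.append(py)
        x, y = np.concatenate(xs), np.concatenate(ys)
    dims = rng.choice(cfg.dimensions, size=(n, 2), replace=True)
    width = len(str(max(n_participants, 1)))
    participant = np.repeat(
        np.array([f"P{i + 1:0{width}d}" for i in range(n_participants)]), clicks
    )
    return _assemble(participant, x, y, dims, cfg)


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("concentric3", "nested_single", "venn3", "two_square")

_CONCENTRIC = [  # squares of side 60/40/20, all centred at (50, 50)
    (20.0, 20.0, 60.0),
    (30.0, 30.0, 40.0),
    (40.0, 40.0, 20.0),
]


def fixtures(name: str, region: str = "front") -> DrawingSet:
    """Small deterministic drawing sets.

    * ``concentric3`` — three strictly nested squares by three distinct
      participants A/B/C (decomposes into 9 rectangles);
    * ``nested_single`` — the same squares by one participant
      (collapses to 1 rectangle);
    * ``venn3`` — three mutually overlapping squares with a nonempty
      triple intersection (proportions 1/3, 2/3, 3/3);
    * ``two_square`` — the worked pair (0,0,20,20) and (10,10,20,20)
      by two participants (5 rectangles, horizontal layout).
    """
    if name == "concentric3":
        recs = [
            PainRecording(p, x, y, s, s, region, order=i)
            for i, (p, (x, y, s)) in enumerate(zip("ABC", _CONCENTRIC))
        ]
        return DrawingSet.from_recordings(recs, total_drawings=3, region=region)
    if name == "nested_single":
        recs = [
            PainRecording("A", x, y, s, s, region, order=i)
            for i, (x, y, s) in enumerate(_CONCENTRIC)
        ]
        return DrawingSet.from_recordings(recs, total_drawings=1, region=region)
    if name == "venn3":
        geoms = [
            ("A", 0.0, 0.0, 40.0),
            ("B", 20.0, 10.0, 40.0),
            ("C", 10.0, 20.0, 40.0),
        ]
        recs = [
            PainRecording(p, x, y, s, s, region, order=i)
            for i, (p, x, y, s) in enumerate(geoms)
        ]
        return DrawingSet.from_recordings(recs, total_drawings=3, region=region)
    if name == "two_square":
        recs = [
            PainRecording("a", 0.0, 0.0, 20.0, 20.0, region, order=0),
            PainRecording("b", 10.0, 10.0, 20.0, 20.0, region, order=1),
        ]
        return DrawingSet.from_recordings(recs, total_drawings=2, region=region)
    raise ContractError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
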