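"""Simulation workload generators: sampling laws and determinism."""

from __future__ import annotations

import io

import numpy as np
import pytest

from painmap import (
    ContractError,
    SimulationConfig,
    fixtures,
    rasterize_oracle,
    simulate_participants,
    simulate_single_click,
)
from painmap.svgio import write_recordings_csv


class TestSingleClick:
    def test_shape_and_distinct_participants(self):
        frame = simulate_single_click(500, seed=3)
        assert len(frame) == 500
        assert frame["participant"].nunique() == 500
        assert set(frame["region"]) == {"xy-plane"}

    def test_dimension_values_from_pencil_sequence(self):
        frame = simulate_single_click(2000, seed=3)
        allowed = set(range(10, 101, 10))
        assert set(frame["width"]).issubset(allowed)
        assert set(frame["height"]).issubset(allowed)

    def test_origins_unique(self):
        frame = simulate_single_click(5000, seed=3)
        assert not frame.duplicated(subset=["x", "y"]).any()

    def test_origins_within_plane(self):
        frame = simulate_single_click(1000, seed=3)
        assert frame["x"].between(0, 999).all()
        assert frame["y"].between(0, 999).all()

    def test_dimension_frequencies_uniform(self):
        # 10,000 draws per axis; each of the 10 sizes expected 1000 times,
        # sd = sqrt(n p (1-p)) ~ 30; allow 5 sd.
        frame = simulate_single_click(10_000, seed=11)
        for col in ("width", "height"):
            counts = frame[col].value_counts()
            assert len(counts) == 10
            assert ((counts - 1000).abs() < 150).all()

    def test_too_many_rects_rejected(self):
        cfg = SimulationConfig(plane_width=10, plane_height=10)
        with pytest.raises(ContractError):
            simulate_single_click(101, cfg)

    def test_deterministic_bytes(self):
        out = []
        for _ in range(2):
            buf = io.StringIO()
            frame = simulate_single_click(300, seed=42)
            write_recordings_csv(frame.assign(visibility="visible"), buf,
                                 metadata={"seed": 42})
            out.append(buf.getvalue())
        assert out[0] == out[1]
        assert out[0].startswith("# seed=42\n")


class TestParticipants:
    def test_row_counts(self):
        frame = simulate_participants(10, clicks=100, seed=5)
        assert len(frame) == 1000
        assert (frame.groupby("participant").size() == 100).all()

    def test_dataset_scope_origins_distinct(self):
        frame = simulate_participants(20, clicks=50, seed=5)
        assert not frame.duplicated(subset=["x", "y"]).any()

    def test_participant_scope_allows_cross_participant_collisions(self):
        cfg = SimulationConfig(plane_width=20, plane_height=20)
        frame = simulate_participants(
            5, clicks=100, cfg=cfg, seed=5,
            origins_without_replacement="participant",
        )
        # within a participant: distinct; dataset-wide draws exceed the plane
        assert not frame.groupby("participant")[["x", "y"]].apply(
            lambda g: g.duplicated().any()
        ).any()
        assert len(frame) == 500 > cfg.n_origins


class TestFixtures:
    @pytest.mark.parametrize(
        "name, n_recs, n_participants, total",
        [
            ("concentric3", 3, 3, 3),
            ("nested_single", 3, 1, 1),
            ("venn3", 3, 3, 3),
            ("two_square", 2, 2, 2),
        ],
    )
    def test_counts(self, name, n_recs, n_participants, total):
        ds = fixtures(name)
        assert len(ds.recordings) == n_recs
        assert len(ds.participants) == n_participants
        assert ds.total_drawings == total

    def test_venn3_has_triple_intersection(self):
        ds = fixtures("venn3")
        po = rasterize_oracle(ds.recordings)
        triple = [v for k, v in po.area_by_set().items() if len(k) == 3]
        assert triple and triple[0] > 0

    def test_unknown_name_rejected(self):
        with pytest.raises(ContractError):
            fixtures("nope")
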