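"""Phantom generator: geometry, labels, determinism, learnable signal."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lus_abline as la
from lus_abline.phantom import (
    make_frame_labels,
    severity_from_geometry,
    simulate_frame_probabilities,
)

from conftest import labelled_frames, oracle_label, ray_energy_score, RAY_SCORE_THRESHOLD


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"image_height": 0},
            {"pleural_depth_fraction": 0.04},
            {"pleural_depth_fraction": 0.6},
            {"b_line_count": -1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            la.PhantomConfig(**kwargs)


class TestGenerateFrame:
    def test_a_frame_has_no_vertical_ray(self, cfg128):
        f = la.generate_frame(
            dataclasses.replace(cfg128, b_line_count=0), "A", rng=1
        )
        assert ray_energy_score(f.pixels, cfg128) < RAY_SCORE_THRESHOLD

    def test_wide_rays_past_half_pleura_are_severe(self, cfg128):
        # 4 rays of 10 px at a ~67 px pleural arc occupy > 50%
        cfg = dataclasses.replace(cfg128, b_line_count=4, b_line_width=10.0)
        coverage = 4 * cfg.b_line_width / cfg.pleural_arc_length()
        assert coverage > 0.5
        assert severity_from_geometry(cfg, 4) == "severe"

    def test_seed_determinism(self, cfg128):
        f1 = la.generate_frame(cfg128, "B", rng=42)
        f2 = la.generate_frame(cfg128, "B", rng=42)
        np.testing.assert_array_equal(f1.pixels, f2.pixels)

    def test_intensity_and_mask_invariants(self, cfg128):
        for lab in ("A", "B"):
            f = la.generate_frame(cfg128, lab, rng=3)
            assert f.pixels.min() >= 0.0 and f.pixels.max() <= 1.0
            assert np.all(f.pixels[~cfg128.sector_mask()] == 0.0)

    def test_invalid_label_rejected(self, cfg128):
        with pytest.raises(ValueError, match="frame_label"):
            la.generate_frame(cfg128, "C")


class TestClipSpec:
    def test_homogeneous_b_clip_all_b_frames(self):
        spec = la.ClipSpec("P0", "P0C0", "B", "moderate", "homogeneous", 30, ("B",) * 30)
        assert all(l == "B" for l in spec.frame_labels)

    def test_heterogeneous_run_structure(self):
        labels = ("A",) * 10 + ("B",) * 10 + ("A",) * 10
        spec = la.ClipSpec("P0", "P0C1", "B", "mild", "heterogeneous", 30, labels)
        assert spec.clip_label == "B"
        assert sum(l == "B" for l in spec.frame_labels) == 10

    @pytest.mark.parametrize(
        "label,severity,homogeneity,labels",
        [
            ("B", "mild", "homogeneous", ("A",) * 5 + ("B",) * 5),  # flag contradiction
            ("A", "none", "heterogeneous", ("A",) * 10),  # heterogeneous A
            ("A", "none", "homogeneous", ("B",) * 10),  # label mismatch
            ("B", "none", "homogeneous", ("B",) * 10),  # severity none on B
        ],
    )
    def test_inconsistent_specs_rejected(self, label, severity, homogeneity, labels):
        with pytest.raises(ValueError):
            la.ClipSpec("P0", "C0", label, severity, homogeneity, len(labels), labels)


class TestGenerateClip:
    def test_frames_realize_labels_and_share_mask(self, cfg64):
        labels = make_frame_labels(24, "B", "heterogeneous", np.random.default_rng(5))
        spec = la.ClipSpec("P1", "P1C0", "B", "moderate", "heterogeneous", 24, labels)
        clip = la.generate_clip(cfg64, spec)
        mask = cfg64.sector_mask()
        for frame, lab in zip(clip.frames, labels):
            assert frame.frame_label == lab
            assert oracle_label(frame.pixels, cfg64) == lab
            assert np.all(frame.pixels[~mask] == 0.0)

    def test_clip_determinism(self, cfg64):
        spec = la.ClipSpec("P1", "P1C9", "B", "severe", "homogeneous", 8, ("B",) * 8)
        c1 = la.generate_clip(cfg64, spec)
        c2 = la.generate_clip(cfg64, spec)
        np.testing.assert_array_equal(c1.pixel_stack(), c2.pixel_stack())


class TestCohort:
    def test_every_clip_belongs_to_one_patient(self):
        cohort = la.generate_cohort(40, (2, 4), seed=1)
        m = cohort.manifest
        assert m["clip_id"].is_unique
        assert m.groupby("clip_id")["patient_id"].nunique().eq(1).all()
        assert 2 <= m.groupby("patient_id").size().min()
        assert m.groupby("patient_id").size().max() <= 4

    def test_all_a_mix_has_no_b_clips(self):
        cohort = la.generate_cohort(10, class_mix=0.0, seed=2)
        assert (cohort.manifest["clip_label"] == "A").all()

    def test_zero_heterogeneous_fraction(self):
        cohort = la.generate_cohort(10, heterogeneous_fraction=0.0, seed=3)
        assert (cohort.manifest["homogeneity"] == "homogeneous").all()

    def test_manifest_determinism(self):
        m1 = la.generate_cohort(15, seed=7).manifest
        m2 = la.generate_cohort(15, seed=7).manifest
        pd.testing.assert_frame_equal(m1, m2)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            la.generate_cohort(5, class_mix=1.5)


class TestSeverityConsistency:
    def test_severity_recomputed_from_geometry_matches(self, cfg64):
        """Requested severity always matches the rendered ray geometry."""
        rng = np.random.default_rng(0)
        for i in range(100):
            severity = ["mild", "moderate", "severe"][i % 3]
            spec = la.ClipSpec(
                "P9", f"S{i:03d}", "B", severity, "homogeneous", 2, ("B", "B")
            )
            clip = la.generate_clip(cfg64, spec)
            n_rays = len(clip.ray_angles)
            assert severity_from_geometry(cfg64, n_rays) == severity
            # rays must be rendered distinct: count angular-profile peaks
            frame = clip.frames[0]
            assert frame.ray_mask.sum() > 0


class TestOracleSeparability:
    def test_phantom_carries_learnable_signal(self, cfg64):
        """A simple ray-energy oracle separates A/B frames at >= 99%."""
        X, y, _ = labelled_frames(cfg64, 1000, seed=123)
        correct = sum(
            oracle_label(X[i], cfg64) == ("B" if y[i] else "A") for i in range(len(y))
        )
        assert correct / len(y) >= 0.99


class TestSimulatedProbabilities:
    def test_tracks_labels(self):
        labels = ("A",) * 5 + ("B",) * 5
        p = simulate_frame_probabilities(labels, rng=np.random.default_rng(0))
        assert p.shape == (10,)
        assert p[:5].max() < 0.5 < p[5:].min()

    def test_spikes_only_on_a_frames(self):
        labels = ("A",) * 200
        p = simulate_frame_probabilities(
            labels, spike_rate=0.1, rng=np.random.default_rng(1)
        )
        assert ((p > 0.5).mean()) == pytest.approx(0.1, abs=0.08)
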