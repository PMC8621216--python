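"""Contiguity decision rule, averaging baseline, and the (t, tau) sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lus_abline as la
from lus_abline.clip_infer import (
    ClipProbabilities,
    ThresholdSetting,
    classify_clip,
    classify_clip_averaging,
    select_operating_point,
    sweep,
)


def brute_force_decision(pB, t, tau):
    """All-windows scan: reference oracle for the contiguity rule."""
    pB = np.asarray(pB)
    n = len(pB)
    if n < tau:
        return 0, None
    win = np.lib.stride_tricks.sliding_window_view(pB, tau)
    hits = np.flatnonzero((win >= t).all(axis=1))
    if hits.size:
        return 1, (int(hits[0]), int(hits[0] + tau - 1))
    return 0, None


class TestClassifyClip:
    @pytest.mark.parametrize(
        "pB,t,tau,want,window",
        [
            ([0.9, 0.8, 0.95], 0.7, 3, 1, (0, 2)),  # all frames above t
            ([0.9, 0.6, 0.9, 0.9], 0.7, 2, 1, (2, 3)),  # only last pair runs
            ([0.9, 0.6, 0.9], 0.7, 2, 0, None),  # no run of 2
            ([0.5, 0.5], 0.5, 3, 0, None),  # clip shorter than tau
            ([0.7, 0.7], 0.7, 1, 1, (0, 0)),  # inclusive comparison
        ],
    )
    def test_hand_examples(self, pB, t, tau, want, window):
        d = classify_clip(ClipProbabilities(pB), ThresholdSetting(t=t, tau=tau))
        assert d.y_hat == want
        assert d.triggering_window == window

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pB = rng.random(int(rng.integers(1, 61)))
            probs = ClipProbabilities(pB)
            for t in (0.5, 0.7, 0.9):
                for tau in (1, 2, 3, 5, 10, 40):
                    got = classify_clip(probs, ThresholdSetting(t=t, tau=tau))
                    want, window = brute_force_decision(pB, t, tau)
                    assert got.y_hat == want
                    assert got.triggering_window == window

    def test_tau_one_reduces_to_max_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pB = rng.random(20)
            d = classify_clip(ClipProbabilities(pB), ThresholdSetting(t=0.8, tau=1))
            assert d.y_hat == int(pB.max() >= 0.8)

    def test_invariant_to_lowering_outside_window(self):
        pB = np.array([0.2, 0.9, 0.95, 0.9, 0.4, 0.8])
        setting = ThresholdSetting(t=0.7, tau=3)
        d = classify_clip(ClipProbabilities(pB), setting)
        assert d.y_hat == 1
        lo, hi = d.triggering_window
        lowered = pB.copy()
        outside = np.ones(len(pB), bool)
        outside[lo : hi + 1] = False
        lowered[outside] = 0.0
        d2 = classify_clip(ClipProbabilities(lowered), setting)
        assert (d2.y_hat, d2.triggering_window) == (1, (lo, hi))

    @given(
        pB=st.lists(st.floats(0, 1), min_size=1, max_size=60),
        t=st.sampled_from([0.5, 0.6, 0.7, 0.8, 0.9]),
        tau=st.integers(1, 40),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_monotone_in_thresholds(self, pB, t, tau):
        """A B-positive call survives any loosening of (t, tau)."""
        probs = ClipProbabilities(np.array(pB))
        if classify_clip(probs, ThresholdSetting(t=t, tau=tau)).y_hat == 1:
            for t2 in (0.5, t):
                for tau2 in (1, max(1, tau - 1), tau):
                    assert (
                        classify_clip(probs, ThresholdSetting(t=t2, tau=tau2)).y_hat == 1
                    )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ClipProbabilities(np.array([]))

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSetting(t=0.4, tau=1)
        with pytest.raises(ValueError):
            ThresholdSetting(t=0.7, tau=0)


class TestAveraging:
    def test_all_ones(self):
        d = classify_clip_averaging(ClipProbabilities([1.0] * 10))
        assert d.y_hat == 1

    def test_boundary_inclusive(self):
        assert classify_clip_averaging(ClipProbabilities([0.5] * 7), 0.5).y_hat == 1

    def test_heterogeneous_clip_false_negative_vs_contiguity(self):
        """Short high-probability run in a long normal background: the
        mean dilutes to 0.26 and averaging calls A, while the
        contiguity rule at (t=0.7, tau=3) recovers the B call."""
        pB = np.array([0.9] * 10 + [0.1] * 40)
        probs = ClipProbabilities(pB)
        assert probs.pB.mean() == pytest.approx(0.26)
        assert classify_clip_averaging(probs, 0.5).y_hat == 0
        assert classify_clip(probs, ThresholdSetting(t=0.7, tau=3)).y_hat == 1


def hand_built_clips():
    a = ClipProbabilities([0.6] * 20, clip_id="a", ground_truth="A")
    b_run = ClipProbabilities(
        [0.1] * 5 + [0.95] * 5 + [0.1] * 10, clip_id="b_run", ground_truth="B"
    )
    b_spikes = ClipProbabilities(
        [0.1, 0.95, 0.1, 0.95, 0.1, 0.95] + [0.1] * 14,
        clip_id="b_spikes",
        ground_truth="B",
    )
    return [a, b_run, b_spikes]


class TestSweep:
    def test_hand_enumerated_surface(self):
        result = sweep(hand_built_clips(), t_values=(0.9,), tau_values=(1, 3))
        assert result.sensitivity[0, 0] == 1.0  # tau=1 catches both B clips
        assert result.sensitivity[0, 1] == 0.5  # tau=3 loses the spike clip
        np.testing.assert_array_equal(result.specificity, 1.0)

    def test_perfect_clips_saturate_grid(self):
        clips = [
            ClipProbabilities([1.0] * 45, clip_id="b", ground_truth="B"),
            ClipProbabilities([0.0] * 45, clip_id="a", ground_truth="A"),
        ]
        res = sweep(clips, tau_values=range(1, 41))
        np.testing.assert_array_equal(res.sensitivity, 1.0)
        np.testing.assert_array_equal(res.specificity, 1.0)

    def test_dataset_monotonicity_along_tau_and_t(self):
        rng = np.random.default_rng(2)
        clips = []
        for i in range(60):
            gt = "B" if i % 2 else "A"
            labels = ("B",) * int(rng.integers(3, 10)) + ("A",) * 30 if gt == "B" else ("A",) * 36
            pB = la.phantom.simulate_frame_probabilities(
                labels, spike_rate=0.05, rng=rng
            )
            clips.append(ClipProbabilities(pB, clip_id=str(i), ground_truth=gt))
        res = sweep(clips, tau_values=range(1, 16))
        assert np.all(np.diff(res.sensitivity, axis=1) <= 1e-12)  # tau direction
        assert np.all(np.diff(res.specificity, axis=1) >= -1e-12)
        assert np.all(np.diff(res.sensitivity, axis=0) <= 1e-12)  # t direction
        assert np.all(np.diff(res.specificity, axis=0) >= -1e-12)

    def test_single_class_rejected(self):
        clips = [ClipProbabilities([0.9] * 5, ground_truth="B")]
        with pytest.raises(ValueError, match="both"):
            sweep(clips)

    def test_round_trip_table(self):
        res = sweep(hand_built_clips(), t_values=(0.5, 0.9), tau_values=(1, 2, 3))
        df = res.to_frame()
        assert len(df) == 6
        assert set(df.columns) == {"t", "tau", "sensitivity", "specificity"}


class TestOperatingPoint:
    def test_unique_maximizer_selected(self):
        res = sweep(hand_built_clips(), t_values=(0.5, 0.9), tau_values=(1, 3))
        op = select_operating_point(res)
        assert (op.t, op.tau) == (0.9, 1)  # sens 1.0 + spec 1.0 only there

    def test_tie_breaks_to_smaller_tau_then_t(self):
        flat = la.SweepResult(
            t_values=(0.5, 0.7),
            tau_values=(2, 5),
            sensitivity=np.full((2, 2), 0.8),
            specificity=np.full((2, 2), 0.8),
        )
        op = select_operating_point(flat)
        assert (op.t, op.tau) == (0.5, 2)

    def test_spiky_a_clips_push_tau_above_one(self):
        """Isolated false-positive spikes on normal clips defeat tau=1."""
        rng = np.random.default_rng(3)
        clips = []
        for i in range(40):
            labels = ("B",) * 6 + ("A",) * 30
            pB = la.phantom.simulate_frame_probabilities(labels, rng=rng)
            clips.append(ClipProbabilities(pB, clip_id=f"b{i}", ground_truth="B"))
        for i in range(40):
            pB = la.phantom.simulate_frame_probabilities(
                ("A",) * 36, spike_rate=0.05, rng=rng
            )
            clips.append(ClipProbabilities(pB, clip_id=f"a{i}", ground_truth="A"))
        res = sweep(clips, tau_values=range(1, 11))
        op = select_operating_point(res)
        assert op.tau > 1
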