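"""Clip-level classification from frame-wise B-line probabilities.

A clip is called B-positive when at least one window of tau
consecutive frames all have B-line probability >= t:

    y_hat = 1[ OR_{i=1..n-tau+1} ( AND_{j=i..i+tau-1} pB_j >= t ) ]

with two hyperparameters: the classification threshold t (minimum
B-line probability for a frame to count as a B frame) and the
contiguity threshold tau (minimum run of consecutive B frames).
The comparison is inclusive (pB >= t), and a clip shorter than tau
frames is called A: the disjunction over window starts is empty.

The contiguity rule exists because of heterogeneous clips, where
pathological B lines come in and out of view with tidal respiration
and most frames show A lines: simple clip averaging of pB dilutes the
short B runs below threshold and returns a falsely negative "normal"
call. Requiring a short contiguous run instead catches those clips
while isolated single-frame false positives (defeated by tau > 1)
keep specificity high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClipProbabilities",
    "ThresholdSetting",
    "ClipDecision",
    "SweepResult",
    "classify_clip",
    "classify_clip_averaging",
    "sweep",
    "select_operating_point",
    "DEFAULT_T_GRID",
    "DEFAULT_TAU_GRID",
]

DEFAULT_T_GRID = (0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_TAU_GRID = tuple(range(1, 41))


@dataclass
class ClipProbabilities:
    """Ordered per-frame B-line probabilities for one clip."""

    pB: np.ndarray
    clip_id: str = ""
    ground_truth: str | None = None  # "A" / "B" when known

    def __post_init__(self):
        self.pB = np.asarray(self.pB, dtype=float)
        if self.pB.ndim != 1 or self.pB.size < 1:
            raise ValueError("pB must be a non-empty 1-D sequence")
        if np.any((self.pB < 0) | (self.pB > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.ground_truth is not None and self.ground_truth not in ("A", "B"):
            raise ValueError("ground_truth must be 'A' or 'B'")

    @property
    def n(self) -> int:
        return self.pB.size


@dataclass(frozen=True)
class ThresholdSetting:
    t: float
    tau: int

    def __post_init__(self):
        if not 0.5 <= self.t < 1.0:
            raise ValueError(f"classification threshold t must be in [0.5, 1), got {self.t}")
        if self.tau < 1 or int(self.tau) != self.tau:
            raise ValueError(f"contiguity threshold tau must be a positive integer, got {self.tau}")


@dataclass
class ClipDecision:
    y_hat: int  # 0 = A, 1 = B
    triggering_window: tuple | None = None  # (start, end) 0-based inclusive

    def __post_init__(self):
        if self.y_hat not in (0, 1):
            raise ValueError("y_hat must be 0 or 1")
        if (self.y_hat == 1) != (self.triggering_window is not None):
            raise ValueError("triggering window present iff the call is B")

    @property
    def label(self) -> str:
        return "B" if self.y_hat else "A"


def classify_clip(probs: ClipProbabilities, setting: ThresholdSetting) -> ClipDecision:
    """Contiguity decision rule; reports the earliest triggering window.

    Implemented by run-length encoding the boolean mask pB >= t: the
    clip is B-positive iff some run of above-threshold frames reaches
    length tau, and the earliest window is the first tau frames of the
    first such run.
    """
    p = probs.pB
    tau = int(setting.tau)
    if p.size < tau:
        return ClipDecision(y_hat=0)
    above = p >= setting.t
    # run-length encode: boundaries where the mask changes value
    change = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [above.size]))  # exclusive
    for s, e in zip(starts, ends):
        if above[s] and e - s >= tau:
            return ClipDecision(y_hat=1, triggering_window=(int(s), int(s + tau - 1)))
    return ClipDecision(y_hat=0)


def classify_clip_averaging(
    probs: ClipProbabilities, threshold: float = 0.5
) -> ClipDecision:
    """Baseline: B-positive iff the mean frame probability >= threshold.

    Appropriate for homogeneous clips; on heterogeneous clips the long
    A-line background dilutes the mean and the call is falsely negative.
    """
    mean = float(probs.pB.mean())
    if mean >= threshold:
        return ClipDecision(y_hat=1, triggering_window=(0, probs.n - 1))
    return ClipDecision(y_hat=0)


@dataclass
class SweepResult:
    """Sensitivity/specificity surfaces over the (t, tau) grid."""

    t_values: tuple
    tau_values: tuple
    sensitivity: np.ndarray  # (len(t), len(tau))
    specificity: np.ndarray

    def __post_init__(self):
        for surf in (self.sensitivity, self.specificity):
            if surf.shape != (len(self.t_values), len(self.tau_values)):
                raise ValueError("surface shape must match the grid")
            if np.any((surf < 0) | (surf > 1)):
                raise ValueError("rates must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.t_values):
            for j, tau in enumerate(self.tau_values):
                rows.append(
                    {
                        "t": t,
                        "tau": tau,
                        "sensitivity": self.sensitivity[i, j],
                        "specificity": self.specificity[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def plot(self, path=None):
        """Sensitivity/specificity vs tau, one curve pair per t."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(self.t_values), figsize=(3 * len(self.t_values), 3), sharey=True)
        axes = np.atleast_1d(axes)
        for i, (t, ax) in enumerate(zip(self.t_values, axes)):
            ax.plot(self.tau_values, self.sensitivity[i], label="sensitivity")
            ax.plot(self.tau_values, self.specificity[i], label="specificity")
            ax.set_title(f"t = {t}")
            ax.set_xlabel("contiguity threshold tau")
            ax.set_ylim(-0.02, 1.02)
        axes[0].set_ylabel("rate")
        axes[0].legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def sweep(
    clips,
    t_values=DEFAULT_T_GRID,
    tau_values=DEFAULT_TAU_GRID,
) -> SweepResult:
    """Diagnostic sensitivity/specificity over the full (t, tau) grid.

    Sensitivity = TP / (TP + FN) over ground-truth B clips;
    specificity = TN / (TN + FP) over ground-truth A clips.
    """
    clips = list(clips)
    truths = [c.ground_truth for c in clips]
    if any(g is None for g in truths):
        raise ValueError("every clip needs a ground-truth label for a sweep")
    n_pos = sum(g == "B" for g in truths)
    n_neg = sum(g == "A" for g in truths)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("sweep requires both A and B clips")
    t_values = tuple(t_values)
    tau_values = tuple(int(v) for v in tau_values)
    sens = np.zeros((len(t_values), len(tau_values)))
    spec = np.zeros_like(sens)
    for i, t in enumerate(t_values):
        for j, tau in enumerate(tau_values):
            setting = ThresholdSetting(t=t, tau=tau)
            tp = fn = tn = fp = 0
            for c in clips:
                call = classify_clip(c, setting).y_hat
                if c.ground_truth == "B":
                    tp += call
                    fn += 1 - call
                else:
                    fp += call
                    tn += 1 - call
            sens[i, j] = tp / n_pos
            spec[i, j] = tn / n_neg
    return SweepResult(
        t_values=t_values, tau_values=tau_values, sensitivity=sens, specificity=spec
    )


def select_operating_point(result: SweepResult, criterion=None) -> ThresholdSetting:
    """Grid point maximizing the criterion (default: sensitivity + specificity).

    Ties are broken toward smaller tau, then smaller t.
    """
    if criterion is None:
        def criterion(sens, spec):
            return sens + spec

    score = criterion(result.sensitivity, result.specificity)
    best = -np.inf
    best_setting = None
    for j, tau in enumerate(result.tau_values):  # tau-major: smaller tau wins ties
        for i, t in enumerate(result.t_values):
            if score[i, j] > best + 1e-12:
                best = score[i, j]
                best_setting = ThresholdSetting(t=t, tau=tau)
    return best_setting
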