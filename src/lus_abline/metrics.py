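"""Frame- and clip-level evaluation metrics.

B-line (abnormal) is the positive class throughout. ROC/AUC is
delegated to scikit-learn; the remaining quantities are closed-form
functions of the confusion counts. Cross-validation reports aggregate
per-fold metrics as mean and sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "roc_auc",
    "confusion",
    "report",
    "aggregate_folds",
    "format_report_table",
]

METRIC_NAMES = ("accuracy", "auc", "precision", "recall_sensitivity", "f1", "specificity")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    sensitivity = recall

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_array(self) -> np.ndarray:
        """2x2 array, rows = truth (A, B), cols = predicted (A, B)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def render(self, path) -> None:
        """Write the matrix as a simple annotated heatmap PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.to_array()
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(m, cmap="Blues")
        for (i, j), v in np.ndenumerate(m):
            ax.text(j, i, str(v), ha="center", va="center")
        ax.set_xticks([0, 1], ["A", "B"])
        ax.set_yticks([0, 1], ["A", "B"])
        ax.set_xlabel("predicted")
        ax.set_ylabel("truth")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class MetricReport:
    accuracy: float
    auc: float
    precision: float
    recall_sensitivity: float
    f1: float
    specificity: float
    sd: dict | None = None  # per-metric SD when aggregated across folds

    def __post_init__(self):
        p, r = self.precision, self.recall_sensitivity
        if np.isfinite(p) and np.isfinite(r) and (p + r) > 0 and self.sd is None:
            if abs(self.f1 - 2 * p * r / (p + r)) > 1e-9:
                raise ValueError("f1 must equal the harmonic mean of precision and recall")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def roc_auc(scores, labels) -> tuple:
    """AUC plus ROC curve points (fpr, tpr) for B-line scores.

    labels: 1/0 or "B"/"A". Equals the Mann-Whitney U statistic
    normalized by n_pos * n_neg, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (1, "B") else 0 for l in np.asarray(labels).ravel()])
    if len(scores) != len(y):
        raise ValueError("scores and labels must be aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return float(_sk_auc(fpr, tpr)), fpr, tpr


def confusion(predictions, labels) -> ConfusionMatrix:
    """Confusion counts with B as positive; inputs as "A"/"B" or 1/0."""
    pred = np.asarray([1 if p in (1, "B") else 0 for p in np.asarray(predictions).ravel()])
    y = np.asarray([1 if l in (1, "B") else 0 for l in np.asarray(labels).ravel()])
    if len(pred) != len(y):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(y)} labels")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def report(cm: ConfusionMatrix, auc_value: float = float("nan")) -> MetricReport:
    return MetricReport(
        accuracy=cm.accuracy,
        auc=auc_value,
        precision=cm.precision,
        recall_sensitivity=cm.recall,
        f1=cm.f1,
        specificity=cm.specificity,
    )


def aggregate_folds(reports) -> MetricReport:
    """Mean and sample SD of each metric across fold reports."""
    reports = list(reports)
    if len(reports) < 2:
        raise ValueError("aggregation needs at least two folds")
    values = {name: np.array([getattr(r, name) for r in reports]) for name in METRIC_NAMES}
    means = {name: float(np.nanmean(v)) for name, v in values.items()}
    sds = {name: float(np.nanstd(v, ddof=1)) for name, v in values.items()}
    return MetricReport(sd=sds, **means)


def format_report_table(rows: dict) -> pd.DataFrame:
    """Summary table: one row per data source, mean (SD) per metric."""
    out = {}
    for source, rep in rows.items():
        cells = {}
        for name in METRIC_NAMES:
            v = getattr(rep, name)
            if rep.sd is not None:
                cells[name] = f"{v:.3f} (SD {rep.sd[name]:.3f})"
            else:
                cells[name] = f"{v:.3f}"
        out[source] = cells
    return pd.DataFrame(out).T[list(METRIC_NAMES)]
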