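"""Patient-grouped K-fold partitioning and data-pool routing.

All clips of a patient are confined to one of train/validation/test in
every fold, preventing patient-level leakage. Separately from the fold
machinery, clips are routed into two disjoint pools: homogeneous clips
available at frame-training time feed the frame classifier, while
heterogeneous clips (and homogeneous clips labelled after training,
marked by a batch flag) are reserved for clip-level inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FoldPlan", "make_folds", "route_pools", "fold_frame_summary"]


@dataclass
class FoldPlan:
    k: int
    assignment: dict  # patient_id -> fold index
    folds: list = field(default_factory=list)  # [{train, validation, test}]

    def sets(self, fold: int) -> tuple:
        f = self.folds[fold]
        return f["train"], f["validation"], f["test"]

    def validate(self) -> None:
        patients = set(self.assignment)
        tests = [set(f["test"]) for f in self.folds]
        if set().union(*tests) != patients:
            raise ValueError("union of test sets must cover all patients")
        for f in self.folds:
            tr, va, te = set(f["train"]), set(f["validation"]), set(f["test"])
            if tr & va or tr & te or va & te:
                raise ValueError("train/validation/test patient sets overlap")
            if tr | va | te != patients:
                raise ValueError("fold sets must partition the patients")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "k": self.k,
                    "assignment": self.assignment,
                    "folds": [
                        {k: sorted(v) for k, v in f.items()} for f in self.folds
                    ],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "FoldPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(k=d["k"], assignment=d["assignment"], folds=d["folds"])


def _patient_classes(manifest: pd.DataFrame) -> pd.Series:
    """Majority clip label per patient (ties broken toward B)."""

    def majority(labels):
        b = (labels == "B").sum()
        return "B" if b * 2 >= len(labels) else "A"

    return manifest.groupby("patient_id")["clip_label"].agg(majority)


def make_folds(
    manifest: pd.DataFrame,
    k: int = 10,
    validation_fraction: float = 0.10,
    seed: int = 0,
) -> FoldPlan:
    """Class-stratified, patient-grouped K-fold plan.

    Patients are shuffled within class and dealt round-robin to folds,
    so both classes appear in every test set. For fold *i*, its
    patients are the test set; validation patients are drawn
    (per class) from the remainder, and the rest train.
    """
    classes = _patient_classes(manifest)
    counts = classes.value_counts()
    for cls in ("A", "B"):
        if counts.get(cls, 0) < k:
            raise ValueError(
                f"need at least k={k} patients of class {cls}, "
                f"found {counts.get(cls, 0)}"
            )
    rng = np.random.default_rng(seed)
    assignment = {}
    for cls, group in classes.groupby(classes):
        ids = sorted(group.index)
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            assignment[pid] = i % k
    folds = []
    all_patients = sorted(assignment)
    for f in range(k):
        test = [p for p in all_patients if assignment[p] == f]
        rest = [p for p in all_patients if assignment[p] != f]
        validation = []
        for cls in ("A", "B"):
            pool = [p for p in rest if classes[p] == cls]
            n_val = max(1, int(round(validation_fraction * len(pool))))
            pick = rng.choice(len(pool), size=n_val, replace=False)
            validation.extend(pool[i] for i in sorted(pick))
        train = [p for p in rest if p not in set(validation)]
        folds.append({"train": train, "validation": validation, "test": test})
    plan = FoldPlan(k=k, assignment=assignment, folds=folds)
    plan.validate()
    return plan


def route_pools(manifest: pd.DataFrame, cutoff_marker: int = 0) -> tuple:
    """Split clips into frame-training and clip-inference pools.

    frame_pool: homogeneous clips with batch <= cutoff_marker (available
    when the frame classifier was trained). clip_pool: heterogeneous
    clips plus homogeneous clips labelled later. The pools share no
    clip_id, preventing leakage from frame training into clip inference.
    """
    homog = manifest["homogeneity"] == "homogeneous"
    early = manifest["batch"] <= cutoff_marker
    frame_pool = manifest[homog & early].reset_index(drop=True)
    clip_pool = manifest[~(homog & early)].reset_index(drop=True)
    overlap = set(frame_pool["clip_id"]) & set(clip_pool["clip_id"])
    assert not overlap, f"pool routing produced overlapping clips: {overlap}"
    return frame_pool, clip_pool


def fold_frame_summary(manifest: pd.DataFrame, plan: FoldPlan) -> pd.DataFrame:
    """Mean +/- SD of patients/clips/frames per set across folds, by class."""
    classes = _patient_classes(manifest)
    records = []
    for f in range(plan.k):
        for set_name, patients in zip(("train", "validation", "test"), plan.sets(f)):
            sub = manifest[manifest["patient_id"].isin(patients)]
            for cls in ("A", "B"):
                pts = [p for p in patients if classes.get(p) == cls]
                cl = sub[sub["clip_label"] == cls]
                records.append(
                    {
                        "fold": f,
                        "set": set_name,
                        "class": cls,
                        "patients": len(pts),
                        "clips": len(cl),
                        "frames": int(cl["n_frames"].sum()),
                    }
                )
    df = pd.DataFrame(records)
    return (
        df.groupby(["class", "set"])[["patients", "clips", "frames"]]
        .agg(["mean", "std"])
        .round(2)
    )
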