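"""Frame-level A-line vs B-line classifier.

The network is the first three convolutional blocks of a VGG16-style
architecture — (2, 2, 3) convolution layers of (64, 128, 256) 3x3
filters — with the third block's max-pool removed, so the spatial
downsampling factor is exactly 4. The head is global average pooling,
dropout, and a 2-node fully connected layer with softmax, yielding a
probability pair p = [pA, pB] per frame; the predicted class is
argmax(p). Frames are classified independently: no temporal coupling.

Training is plain mini-batch Adam on softmax cross-entropy with
optional inverse-frequency class weighting, stochastic augmentation of
training batches only, and early stopping on validation loss with the
best-validation checkpoint restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _nn
from .phantom import Clip
from .preprocess import AugmentationRanges, BeamMask, apply_mask, augment

__all__ = [
    "ArchitecturePlan",
    "TrainConfig",
    "FramePrediction",
    "FrameClassifier",
    "build_model",
    "train",
    "predict_frames",
]

CLASS_NAMES = ("A", "B")  # index 0 = A (normal), 1 = B (abnormal)


@dataclass
class ArchitecturePlan:
    """Truncated-VGG layout: conv layers per block, filters, pooling."""

    convs_per_block: tuple = (2, 2, 3)
    filters: tuple = (64, 128, 256)
    pool_after_block: tuple = (True, True, False)  # block 3's pool removed
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        if len(self.convs_per_block) != len(self.filters) or len(self.filters) != len(
            self.pool_after_block
        ):
            raise ValueError("block descriptions must have equal length")
        if sum(self.pool_after_block) != 2:
            raise ValueError("exactly two max-pool stages are required")

    @property
    def downsampling_factor(self) -> int:
        return 2 ** sum(self.pool_after_block)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-4
    dropout_rate: float = 0.5
    early_stopping_patience: int = 3
    class_weighting: bool = True
    pretrained_init: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 0, batch_size >= 1, learning_rate > 0 required")


@dataclass
class FramePrediction:
    pA: float
    pB: float

    def __post_init__(self):
        if not (0.0 <= self.pA <= 1.0 and 0.0 <= self.pB <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if abs(self.pA + self.pB - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")

    @property
    def predicted_class(self) -> str:
        return CLASS_NAMES[int(self.pB > self.pA)]


class FrameClassifier:
    """The truncated-VGG network with explicit forward/backward passes."""

    def __init__(self, plan: ArchitecturePlan, input_shape: tuple, seed: int = 0):
        h, w = input_shape
        f = plan.downsampling_factor
        if h % f or w % f:
            raise ValueError(
                f"input dims {input_shape} must be divisible by {f} "
                f"(two 2x2 pooling stages)"
            )
        self.plan = plan
        self.input_shape = (int(h), int(w))
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = 1
        for n_conv, c_out, pool in zip(
            plan.convs_per_block, plan.filters, plan.pool_after_block
        ):
            for _ in range(n_conv):
                self.layers.append(_nn.Conv3x3(c_in, c_out, rng))
                self.layers.append(_nn.ReLU())
                c_in = c_out
            if pool:
                self.layers.append(_nn.MaxPool2x2())
        self._feature_index = len(self.layers) - 1  # last ReLU of block 3
        self.gap = _nn.GlobalAvgPool()
        self.dropout = _nn.Dropout(plan.dropout_rate)
        self.head = _nn.Dense(plan.filters[-1], plan.n_classes, rng)

    # -- parameter plumbing ---------------------------------------------
    @property
    def params(self) -> list:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend(self.head.params)
        return out

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params)

    def state_dict(self) -> list:
        return [p.copy() for p in self.params]

    def load_state(self, state: list) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s

    def save(self, path) -> None:
        meta = {
            "convs_per_block": list(self.plan.convs_per_block),
            "filters": list(self.plan.filters),
            "pool_after_block": list(self.plan.pool_after_block),
            "dropout_rate": self.plan.dropout_rate,
            "n_classes": self.plan.n_classes,
            "input_shape": list(self.input_shape),
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "FrameClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            plan = ArchitecturePlan(
                convs_per_block=tuple(meta["convs_per_block"]),
                filters=tuple(meta["filters"]),
                pool_after_block=tuple(meta["pool_after_block"]),
                dropout_rate=meta["dropout_rate"],
                n_classes=meta["n_classes"],
            )
            model = cls(plan, tuple(meta["input_shape"]))
            model.load_state([z[f"p{i}"] for i in range(len(model.params))])
        return model

    # -- forward / backward ---------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]  # add channel axis
        if x.shape[2:] != self.input_shape:
            raise ValueError(
                f"frames of shape {x.shape[2:]} do not match model input "
                f"{self.input_shape}"
            )
        return x

    def forward(self, x, train: bool = False, rng=None):
        """Logits (B, 2); set train=True to cache activations for backward."""
        a = self._check_input(x)
        for layer in self.layers:
            a = layer.forward(a, train=train)
        z = self.gap.forward(a, train=train)
        z = self.dropout.forward(z, train=train, rng=rng)
        return self.head.forward(z, train=train)

    def backward(self, dlogits) -> list:
        """Gradients aligned with self.params, given dLoss/dlogits."""
        grads_rev = []
        d, g = self.head.backward(dlogits)
        grads_rev.append(g)
        d, g = self.dropout.backward(d)
        d, g = self.gap.backward(d)
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads_rev.append(g)
        grads = []
        for g in reversed(grads_rev):
            grads.extend(g)
        return grads

    def predict_proba(self, x, batch_size: int = 16) -> np.ndarray:
        """[pA, pB] per frame, in order, batched for memory economy."""
        x = self._check_input(x)
        out = np.empty((len(x), self.plan.n_classes), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = _nn.softmax(self.forward(x[i : i + batch_size]))
        return out

    def features(self, x) -> np.ndarray:
        """Block-3 final convolutional feature maps (post-activation)."""
        a = self._check_input(x)
        for layer in self.layers[: self._feature_index + 1]:
            a = layer.forward(a)
        return a


def build_model(
    plan: ArchitecturePlan | None = None,
    input_shape: tuple = (128, 128),
    seed: int = 0,
    pretrained_init: bool = False,
) -> FrameClassifier:
    if plan is None:
        plan = ArchitecturePlan()
    if pretrained_init:
        raise NotImplementedError(
            "pretrained VGG16 initialization requires an external weight file; "
            "this build trains from random (He) initialization"
        )
    return FrameClassifier(plan, input_shape, seed=seed)


def _evaluate(model, X, y, weights) -> tuple:
    logits = np.concatenate(
        [model.forward(X[i : i + 16]) for i in range(0, len(X), 16)]
    )
    loss, _ = _nn.softmax_cross_entropy(logits, y, weights)
    acc = float((logits.argmax(1) == y).mean())
    return loss, acc


def train(
    model: FrameClassifier,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
    augment_ranges: AugmentationRanges | None = None,
    mask: BeamMask | None = None,
) -> dict:
    """Fit the classifier on labelled frames; returns the training history.

    X: (N, H, W) masked frames in [0, 1]; y: integer labels (0=A, 1=B).
    Augmentation, when given, is applied to training batches only, and
    the beam mask is re-applied after the geometric transforms so
    out-of-sector pixels stay zero. Early stopping monitors validation
    loss; the best-validation weights are restored on return.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    X_val = np.asarray(X_val, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.int64)
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    if cfg.epochs == 0:
        return history
    if len(np.unique(y)) < 2:
        raise ValueError("training pool must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    model.dropout.rate = cfg.dropout_rate
    if cfg.class_weighting:
        freq = np.bincount(y, minlength=2) / len(y)
        class_w = np.where(freq > 0, 0.5 / np.maximum(freq, 1e-12), 0.0)
    else:
        class_w = np.ones(2)
    val_w = class_w[y_val] if len(X_val) else None

    opt = _nn.Adam(model.params, lr=cfg.learning_rate)
    best_state, best_val, patience_left = None, np.inf, cfg.early_stopping_patience
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = X[idx]
            if augment_ranges is not None:
                xb = np.stack([augment(f, augment_ranges, rng) for f in xb])
                if mask is not None:
                    xb = np.stack([apply_mask(f, mask) for f in xb])
            logits = model.forward(xb, train=True, rng=rng)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y[idx], class_w[y[idx]])
            grads = model.backward(dlogits)
            opt.step(grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if len(X_val):
            val_loss, val_acc = _evaluate(model, X_val, y_val, val_w)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if val_loss < best_val - 1e-6:
                best_val, best_state = val_loss, model.state_dict()
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        model.load_state(best_state)
    return history


def predict_frames(model: FrameClassifier, clip) -> list:
    """One FramePrediction per frame, order-preserving and stateless."""
    if isinstance(clip, Clip):
        stack = clip.pixel_stack()
    else:
        stack = np.asarray(clip)
        if stack.ndim == 2:
            stack = stack[None]
    if len(stack) == 0:
        raise ValueError("cannot predict on an empty clip")
    probs = model.predict_proba(stack)
    return [FramePrediction(pA=float(p[0]), pB=float(p[1])) for p in probs]
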