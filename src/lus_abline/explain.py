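"""Grad-CAM heatmaps for the frame classifier.

Attribution targets the final convolutional feature maps of block 3
(the deepest spatial representation, at 1/4 input resolution). The
class score is the pre-softmax logit; with a global-average-pooling
head its gradient with respect to feature map k is constant over
space, so the channel weight is the corresponding dense-layer weight
divided by the map area. The heatmap is the rectified weighted sum of
the maps, bilinearly upsampled to the input size and normalized to a
max of 1 when any activation is positive.

The overlay rendering defaults to the inverted colour convention in
which blue marks the highest importance and red the lowest; the
standard jet (red = high) convention is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .frame_model import CLASS_NAMES, FrameClassifier

__all__ = ["Heatmap", "grad_cam", "render_overlay"]


@dataclass
class Heatmap:
    importance: np.ndarray  # (H, W) >= 0, max 1 when any activation positive
    target_class: str

    def __post_init__(self):
        if np.any(self.importance < 0):
            raise ValueError("importance must be non-negative")
        if self.target_class not in CLASS_NAMES:
            raise ValueError(f"target_class must be one of {CLASS_NAMES}")


def grad_cam(model: FrameClassifier, frame, target_class) -> Heatmap:
    """Class-discriminative localization map for one frame."""
    if isinstance(target_class, str):
        if target_class not in CLASS_NAMES:
            raise ValueError(f"unknown class {target_class!r}")
        class_idx = CLASS_NAMES.index(target_class)
    else:
        class_idx = int(target_class)
        if class_idx not in (0, 1):
            raise ValueError(f"class index must be 0 or 1, got {class_idx}")
    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)

    maps = model.features(pixels)[0]  # (C, h, w)
    c, h, w = maps.shape
    # d(logit_c)/d(map_k) is W[c, k] / (h*w) everywhere (GAP head), so the
    # spatially averaged gradient is exactly that constant.
    alpha = model.head.w[class_idx] / (h * w)  # (C,)
    cam = np.maximum(np.tensordot(alpha, maps, axes=(0, 0)), 0.0)
    cam = resize(cam, pixels.shape, order=1, preserve_range=True, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(importance=cam.astype(np.float64), target_class=CLASS_NAMES[class_idx])


def render_overlay(frame, heatmap: Heatmap, convention: str = "paper", path=None):
    """Overlay the heatmap on the frame; returns an (H, W, 3) uint8 image.

    convention="paper": blue = highest importance, red = lowest;
    convention="standard": ordinary jet, red = highest.
    """
    import matplotlib

    matplotlib.use("Agg")
    cmaps = matplotlib.colormaps

    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    if pixels.shape != heatmap.importance.shape:
        raise ValueError(
            f"frame shape {pixels.shape} does not match heatmap "
            f"{heatmap.importance.shape}"
        )
    if convention == "paper":
        colors = cmaps["jet_r"](heatmap.importance)[..., :3]
    elif convention == "standard":
        colors = cmaps["jet"](heatmap.importance)[..., :3]
    else:
        raise ValueError("convention must be 'paper' or 'standard'")
    gray = np.repeat(pixels[..., None], 3, axis=-1)
    weight = 0.45 * (heatmap.importance[..., None] > 0)
    out = (1 - weight) * gray + weight * colors
    img = (np.clip(out, 0, 1) * 255).astype(np.uint8)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, img)
    return img
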