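"""Beam masking and stochastic training-time augmentation.

Real point-of-care frames carry vendor screen furniture (logos, depth
markers, battery indicators) outside the ultrasound beam; masking
retains only the sector. Synthetic phantom frames are born masked, so
:func:`apply_mask` mainly exists for real-data compatibility and for
testing the pipeline's masking contract.

Augmentation draws, per frame: rotation up to ±45°, translation up to
±10% of each dimension, zoom up to ±10%, a one-sided counterclockwise
shear up to 10°, a fair-coin horizontal flip, and a multiplicative
brightness change up to ±30%. Geometric terms are composed in a fixed
order (rotate → shift → zoom → shear) and applied in a single bilinear
warp with zero fill, followed by flip and brightness; intensities are
clipped back to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon2mask
from skimage.transform import AffineTransform, warp

from .phantom import Frame, PhantomConfig

__all__ = ["AugmentationRanges", "BeamMask", "apply_mask", "augment"]


@dataclass
class AugmentationRanges:
    rotation_max: float = 45.0  # degrees, symmetric
    shift_max: float = 0.10  # fraction of each dimension, symmetric
    zoom_max: float = 0.10  # fraction, symmetric
    shear_max: float = 10.0  # degrees, one-sided counterclockwise
    horizontal_flip: bool = True
    brightness_max: float = 0.30  # multiplicative fraction, symmetric

    def __post_init__(self):
        for name in ("rotation_max", "shift_max", "zoom_max", "shear_max", "brightness_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentationRanges":
        return cls(0.0, 0.0, 0.0, 0.0, False, 0.0)


@dataclass
class BeamMask:
    """Sector polygon in pixel coordinates (origin top-left, (row, col))."""

    polygon: np.ndarray  # (N, 2) vertices
    image_shape: tuple  # (H, W)

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon must be an (N>=3, 2) vertex array")
        if _self_intersects(self.polygon):
            raise ValueError("mask polygon must be simple (non-self-intersecting)")
        if self.coverage() <= 0.20:
            raise ValueError(
                f"mask covers {self.coverage():.1%} of the image; must exceed 20%"
            )

    def interior(self) -> np.ndarray:
        return polygon2mask(self.image_shape, self.polygon)

    def coverage(self) -> float:
        return float(self.interior().mean())

    @classmethod
    def from_sector(cls, cfg: PhantomConfig, n_arc: int = 40) -> "BeamMask":
        """Polygonal approximation of cfg's fan-shaped field of view."""
        ay, ax = cfg.apex
        half = np.deg2rad(cfg.sector_angle / 2.0)
        th = np.linspace(-half, half, n_arc)
        near = np.stack([ay + cfg.near_radius * np.cos(th), ax + cfg.near_radius * np.sin(th)], 1)
        far = np.stack([ay + cfg.far_radius * np.cos(th), ax + cfg.far_radius * np.sin(th)], 1)
        poly = np.vstack([near, far[::-1]])
        return cls(polygon=poly, image_shape=(cfg.image_height, cfg.image_width))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"polygon": self.polygon.tolist(), "image_shape": list(self.image_shape)},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "BeamMask":
        with open(path) as fh:
            d = json.load(fh)
        return cls(polygon=np.array(d["polygon"]), image_shape=tuple(d["image_shape"]))


def _self_intersects(poly: np.ndarray) -> bool:
    """Check polygon edges for proper crossings (O(n^2) segment test)."""

    def ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            p1, p2 = edges[i]
            p3, p4 = edges[j]
            d1, d2 = ccw(p3, p4, p1), ccw(p3, p4, p2)
            d3, d4 = ccw(p1, p2, p3), ccw(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return True
    return False


def _pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame)


def _rewrap(frame, pixels: np.ndarray):
    if isinstance(frame, Frame):
        return Frame(pixels=pixels, frame_label=frame.frame_label, ray_mask=frame.ray_mask)
    return pixels


def apply_mask(frame, mask: BeamMask):
    """Zero every pixel outside the beam polygon; idempotent."""
    px = _pixels(frame)
    if px.shape != tuple(mask.image_shape):
        raise ValueError(
            f"frame shape {px.shape} does not match mask shape {tuple(mask.image_shape)}"
        )
    out = px.copy()
    out[~mask.interior()] = 0.0
    return _rewrap(frame, out)


def augment(frame, ranges: AugmentationRanges, rng: np.random.Generator):
    """One stochastic augmentation draw; deterministic under a fixed rng."""
    px = _pixels(frame).astype(np.float32)
    h, w = px.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    rot = np.deg2rad(rng.uniform(-ranges.rotation_max, ranges.rotation_max))
    ty = rng.uniform(-ranges.shift_max, ranges.shift_max) * h
    tx = rng.uniform(-ranges.shift_max, ranges.shift_max) * w
    zoom = 1.0 + rng.uniform(-ranges.zoom_max, ranges.zoom_max)
    shear = np.deg2rad(rng.uniform(0.0, ranges.shear_max))
    do_flip = ranges.horizontal_flip and rng.random() < 0.5
    gain = 1.0 + rng.uniform(-ranges.brightness_max, ranges.brightness_max)

    if rot != 0.0 or tx != 0.0 or ty != 0.0 or zoom != 1.0 or shear != 0.0:
        # skimage transforms use (x, y) = (col, row); compose about the center
        center = AffineTransform(translation=(-cx, -cy))
        geo = (
            AffineTransform(rotation=rot)
            + AffineTransform(translation=(tx, ty))
            + AffineTransform(scale=(zoom, zoom))
            + AffineTransform(shear=-shear)
        )
        tform = center + geo + AffineTransform(translation=(cx, cy))
        px = warp(px, tform.inverse, order=1, cval=0.0, preserve_range=True).astype(
            np.float32
        )
    if do_flip:
        px = px[:, ::-1].copy()
    if gain != 1.0:
        px = px * np.float32(gain)
    np.clip(px, 0.0, 1.0, out=px)
    return _rewrap(frame, px)
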