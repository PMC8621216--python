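"""Synthetic sector-scan lung-ultrasound phantom.

Generates fan-shaped grayscale frames carrying the two artifact
families that drive the normal/abnormal parenchyma distinction:

* **A lines** — horizontal reverberation arcs of the pleural line,
  repeating at integer multiples of the pleural depth (normal,
  aerated lung);
* **B lines** — bright vertical rays running from the pleural line
  to the far field (alveolar-interstitial syndrome).

The phantom models only the features a classifier needs — pleural
band, reverberation arcs, radial rays, multiplicative speckle, a
sector mask — not acoustic physics. Clips are ordered frame
sequences; heterogeneous B-line clips modulate ray opacity with a
sinusoidal respiration phase so B lines come in and out of view,
producing contiguous runs of B frames inside an A-frame background.

Severity sublabels follow the clinical convention: *mild* = fewer
than 3 B lines, *moderate* = rays occupying less than 50% of the
pleural-line extent, *severe* = more than 50%.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhantomConfig",
    "ClipSpec",
    "Frame",
    "Clip",
    "Cohort",
    "generate_frame",
    "generate_clip",
    "generate_cohort",
    "make_frame_labels",
    "severity_from_geometry",
    "simulate_frame_probabilities",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "clip_id",
    "path",
    "clip_label",
    "severity",
    "homogeneity",
    "n_frames",
    "batch",
]

_SEVERITIES = ("none", "mild", "moderate", "severe")


@dataclass
class PhantomConfig:
    """Geometry and noise parameters of the phantom.

    Depths are measured from the top of the image along the beam
    (radially from the virtual apex); the pleural line sits at
    ``pleural_depth_fraction`` of the image height, and A-line
    reverberations repeat at integer multiples of that depth.
    """

    image_height: int = 128
    image_width: int = 128
    sector_angle: float = 70.0  # degrees, full opening of the fan
    pleural_depth_fraction: float = 0.25
    n_a_lines: int = 3
    b_line_count: int = 3
    b_line_width: float = 6.0  # pixels at the pleural line
    speckle_sigma: float = 0.08  # multiplicative noise std
    brightness_jitter: float = 0.10  # global gain jitter fraction
    seed: int = 0

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.05 < self.pleural_depth_fraction < 0.5:
            raise ValueError(
                "pleural_depth_fraction must lie in (0.05, 0.5), got "
                f"{self.pleural_depth_fraction}"
            )
        if self.b_line_count < 0:
            raise ValueError("b_line_count must be >= 0")
        if not 10.0 <= self.sector_angle <= 120.0:
            raise ValueError("sector_angle must be in [10, 120] degrees")

    # -- sector geometry -------------------------------------------------
    @property
    def apex(self) -> tuple[float, float]:
        """(row, col) of the virtual transducer apex (above the image)."""
        return (-0.10 * self.image_height, self.image_width / 2.0)

    @property
    def near_radius(self) -> float:
        return 0.18 * self.image_height

    @property
    def far_radius(self) -> float:
        return 1.18 * self.image_height

    @property
    def pleural_depth(self) -> float:
        """Depth of the pleural line below the near field, in pixels."""
        return self.pleural_depth_fraction * self.image_height

    def polar(self):
        """Per-pixel radius and angle grids (angle 0 = straight down)."""
        ay, ax = self.apex
        yy, xx = np.mgrid[0 : self.image_height, 0 : self.image_width]
        r = np.hypot(yy - ay, xx - ax)
        theta = np.arctan2(xx - ax, yy - ay)
        return r.astype(np.float32), theta.astype(np.float32)

    def sector_mask(self) -> np.ndarray:
        r, theta = self.polar()
        half = np.deg2rad(self.sector_angle / 2.0)
        return (
            (np.abs(theta) <= half)
            & (r >= self.near_radius)
            & (r <= self.far_radius)
        )

    def pleural_arc_length(self) -> float:
        """Extent of the pleural line across the sector, in pixels."""
        r_p = self.near_radius + self.pleural_depth
        return np.deg2rad(self.sector_angle) * r_p


def severity_from_geometry(cfg: PhantomConfig, n_rays: int) -> str:
    """Severity sublabel implied by ray count and pleural-line coverage."""
    if n_rays == 0:
        return "none"
    coverage = n_rays * cfg.b_line_width / cfg.pleural_arc_length()
    if n_rays < 3 and coverage < 0.5:
        return "mild"
    if coverage < 0.5:
        return "moderate"
    return "severe"


def _rays_for_severity(cfg: PhantomConfig, severity: str, rng) -> int:
    """Pick a ray count realizing the requested severity under cfg geometry."""
    arc = cfg.pleural_arc_length()
    half_cov = 0.5 * arc / cfg.b_line_width  # ray count at 50% coverage
    if severity == "mild":
        n = int(rng.integers(1, 3))
    elif severity == "moderate":
        lo, hi = 3, max(3, int(np.floor(half_cov - 0.51)))
        n = int(rng.integers(lo, hi + 1))
    elif severity == "severe":
        lo = int(np.ceil(half_cov + 0.51))
        n = int(rng.integers(lo, lo + 3))
    else:
        raise ValueError(f"unknown severity {severity!r}")
    if severity_from_geometry(dataclasses.replace(cfg, b_line_count=n), n) != severity:
        raise ValueError(
            f"cannot realize severity {severity!r} with b_line_width="
            f"{cfg.b_line_width} under this sector geometry"
        )
    return n


@dataclass
class ClipSpec:
    """Ground-truth description of one clip."""

    patient_id: str
    clip_id: str
    clip_label: str  # "A" or "B"
    severity: str  # none | mild | moderate | severe
    homogeneity: str  # homogeneous | heterogeneous
    n_frames: int
    frame_labels: tuple = ()

    def __post_init__(self):
        if self.clip_label not in ("A", "B"):
            raise ValueError(f"clip_label must be 'A' or 'B', got {self.clip_label!r}")
        if self.severity not in _SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.homogeneity not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown homogeneity {self.homogeneity!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.frame_labels = tuple(self.frame_labels)
        if len(self.frame_labels) != self.n_frames:
            raise ValueError("frame_labels length must equal n_frames")
        if any(l not in ("A", "B") for l in self.frame_labels):
            raise ValueError("frame_labels must be 'A'/'B'")
        has_b = "B" in self.frame_labels
        if (self.clip_label == "B") != has_b:
            raise ValueError("clip_label must be B iff some frame is labelled B")
        uniform = len(set(self.frame_labels)) == 1
        if (self.homogeneity == "homogeneous") != uniform:
            raise ValueError("homogeneity flag contradicts frame_labels")
        if self.clip_label == "A" and self.homogeneity == "heterogeneous":
            raise ValueError("heterogeneity only applies to B-line clips")
        if (self.severity == "none") != (self.clip_label == "A"):
            raise ValueError("severity is 'none' iff the clip is A-line")


@dataclass
class Frame:
    """One masked grayscale frame with synthetic ground truth."""

    pixels: np.ndarray  # (H, W) float32 in [0, 1]; 0 outside the sector
    frame_label: str  # "A" or "B"
    ray_mask: np.ndarray | None = None  # bool (H, W): B-ray support

    def __post_init__(self):
        if self.frame_label not in ("A", "B"):
            raise ValueError(f"frame_label must be 'A' or 'B', got {self.frame_label!r}")


@dataclass
class Clip:
    spec: ClipSpec
    frames: list
    ray_angles: np.ndarray | None = None  # fixed ray geometry, B clips only

    def pixel_stack(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])

    def manifest_row(self, path: str = "", batch: int = 0) -> dict:
        s = self.spec
        return {
            "patient_id": s.patient_id,
            "clip_id": s.clip_id,
            "path": path,
            "clip_label": s.clip_label,
            "severity": s.severity,
            "homogeneity": s.homogeneity,
            "n_frames": s.n_frames,
            "batch": batch,
        }


def _sample_ray_angles(cfg: PhantomConfig, n: int, rng) -> np.ndarray:
    """Ray angles (radians), spread over the inner 90% of the sector."""
    half = np.deg2rad(cfg.sector_angle / 2.0) * 0.9
    if n == 0:
        return np.empty(0)
    # evenly spaced slots with random jitter: keeps rays distinct so the
    # recomputed coverage matches the requested one
    slots = np.linspace(-half, half, n + 2)[1:-1]
    gap = (2 * half) / (n + 1)
    jitter = rng.uniform(-0.25, 0.25, size=n) * gap
    return np.sort(slots + jitter)


def generate_frame(
    cfg: PhantomConfig,
    frame_label: str,
    rng: np.random.Generator | int | None = None,
    ray_angles: np.ndarray | None = None,
    ray_opacity: float = 1.0,
) -> Frame:
    """Render one phantom frame.

    A-frames contain the pleural band plus ``n_a_lines`` reverberation
    arcs at integer multiples of the pleural depth. B-frames contain
    the pleural band plus ``b_line_count`` bright rays from the pleural
    line to the far field, with opacity ``ray_opacity`` (heterogeneous
    clips fade rays in and out). Multiplicative speckle and a global
    brightness jitter are applied, then the sector mask.
    """
    if frame_label not in ("A", "B"):
        raise ValueError(f"frame_label must be 'A' or 'B', got {frame_label!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    r, theta = cfg.polar()
    mask = cfg.sector_mask()
    depth = r - cfg.near_radius  # beam depth below the image top

    img = np.full(r.shape, 0.14, dtype=np.float32)  # tissue base

    d_p = cfg.pleural_depth
    band_sigma = 1.6
    # pleural band
    img += 0.75 * np.exp(-((depth - d_p) ** 2) / (2 * band_sigma**2))

    ray_mask = None
    if frame_label == "A":
        for k in range(1, cfg.n_a_lines + 1):
            amp = 0.45 * (0.72**(k - 1))
            img += amp * np.exp(-((depth - (k + 1) * d_p) ** 2) / (2 * band_sigma**2))
    else:
        if ray_angles is None:
            if cfg.b_line_count < 1:
                raise ValueError("B frame requested but cfg.b_line_count < 1")
            ray_angles = _sample_ray_angles(cfg, cfg.b_line_count, rng)
        r_p = cfg.near_radius + d_p
        sigma_theta = (cfg.b_line_width / 2.355) / r_p  # FWHM = b_line_width at pleura
        onset = 1.0 / (1.0 + np.exp(-(depth - d_p) / 2.0))  # rays start at pleura
        ray = np.zeros_like(img)
        for th in np.atleast_1d(ray_angles):
            ray += np.exp(-((theta - th) ** 2) / (2 * sigma_theta**2))
        ray = np.minimum(ray, 1.0) * onset * (0.7 * ray_opacity)
        img += ray
        ray_mask = (ray > 0.25) & mask

    img *= 1.0 + cfg.speckle_sigma * rng.standard_normal(img.shape).astype(np.float32)
    img *= 1.0 + cfg.brightness_jitter * float(rng.uniform(-1.0, 1.0))
    np.clip(img, 0.0, 1.0, out=img)
    img[~mask] = 0.0
    return Frame(pixels=img, frame_label=frame_label, ray_mask=ray_mask)


def make_frame_labels(
    n_frames: int,
    clip_label: str,
    homogeneity: str,
    rng: np.random.Generator,
    respiration_period: float = 20.0,
    visibility_threshold: float = 0.45,
) -> tuple:
    """Per-frame labels; heterogeneous B clips follow a respiration sinusoid.

    A frame is a B frame when ``sin(2*pi*i/period + phase) > threshold``,
    which yields contiguous runs of B frames (B lines sliding into view
    with tidal breathing) inside an A-line background.
    """
    if clip_label == "A":
        return ("A",) * n_frames
    if homogeneity == "homogeneous":
        return ("B",) * n_frames
    phase = rng.uniform(0, 2 * np.pi)
    i = np.arange(n_frames)
    vis = np.sin(2 * np.pi * i / respiration_period + phase)
    labels = np.where(vis > visibility_threshold, "B", "A")
    if "B" not in labels or "A" not in labels:
        # degenerate draw (short clip): force one mid-clip run of B frames
        labels[:] = "A"
        run = max(3, int(round(n_frames * 0.25)))
        start = (n_frames - run) // 2
        labels[start : start + run] = "B"
    return tuple(labels)


def _clip_rng(cfg: PhantomConfig, clip_id: str) -> np.random.Generator:
    return np.random.default_rng(
        (cfg.seed * 0x9E3779B1 + zlib.crc32(clip_id.encode())) % (2**31)
    )


def generate_clip(cfg: PhantomConfig, spec: ClipSpec) -> Clip:
    """Render every frame of a clip.

    Ray geometry is fixed across the clip (the probe does not move);
    in heterogeneous clips the ray opacity follows a half-sine over
    each contiguous B run, so B lines fade in and out of view.
    """
    rng = _clip_rng(cfg, spec.clip_id)
    n_rays = 0
    angles = None
    if spec.clip_label == "B":
        n_rays = _rays_for_severity(cfg, spec.severity, rng)
        angles = _sample_ray_angles(cfg, n_rays, rng)
    cfg_clip = dataclasses.replace(cfg, b_line_count=max(n_rays, cfg.b_line_count))

    labels = np.asarray(spec.frame_labels)
    opacity = np.zeros(spec.n_frames)
    i = 0
    while i < spec.n_frames:  # half-sine opacity per contiguous B run
        if labels[i] == "B":
            j = i
            while j < spec.n_frames and labels[j] == "B":
                j += 1
            run = np.arange(j - i)
            opacity[i:j] = 0.55 + 0.45 * np.sin(np.pi * (run + 0.5) / (j - i))
            i = j
        else:
            i += 1
    if spec.homogeneity == "homogeneous":
        opacity[:] = 1.0

    frames = [
        generate_frame(
            cfg_clip,
            labels[k],
            rng=rng,
            ray_angles=angles,
            ray_opacity=float(opacity[k]),
        )
        for k in range(spec.n_frames)
    ]
    return Clip(spec=spec, frames=frames, ray_angles=angles)


@dataclass
class Cohort:
    """A generated study population: manifest plus renderable clip specs."""

    cfg: PhantomConfig
    manifest: pd.DataFrame
    specs: dict = field(default_factory=dict)

    def render_clip(self, clip_id: str) -> Clip:
        return generate_clip(self.cfg, self.specs[clip_id])

    def write(self, outdir) -> Path:
        """Write PNG frame directories and the manifest CSV."""
        import imageio.v3 as iio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for _, row in self.manifest.iterrows():
            clip = self.render_clip(row["clip_id"])
            cdir = outdir / row["clip_id"]
            cdir.mkdir(exist_ok=True)
            for k, fr in enumerate(clip.frames):
                iio.imwrite(
                    cdir / f"frame_{k:04d}.png",
                    (fr.pixels * 255).astype(np.uint8),
                )
            r = dict(row)
            r["path"] = str(cdir)
            rows.append(r)
        man = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
        man.to_csv(outdir / "manifest.csv", index=False)
        return outdir / "manifest.csv"


def generate_cohort(
    n_patients: int,
    clips_per_patient_range: tuple = (2, 4),
    class_mix: float = 0.5,
    heterogeneous_fraction: float = 0.4,
    late_batch_fraction: float = 0.15,
    n_frames_range: tuple = (30, 60),
    cfg: PhantomConfig | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate a reproducible synthetic study population.

    Each patient carries one dominant parenchymal pattern (drawn B with
    probability ``class_mix``) realized by all of their clips.
    ``heterogeneous_fraction`` of B clips are heterogeneous;
    ``late_batch_fraction`` of homogeneous clips are flagged batch=1
    (labelled after the frame classifier was trained) so the routing
    into frame-training vs clip-inference pools can be exercised.
    """
    for name, frac in (
        ("class_mix", class_mix),
        ("heterogeneous_fraction", heterogeneous_fraction),
        ("late_batch_fraction", late_batch_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    if cfg is None:
        cfg = PhantomConfig(seed=seed)
    else:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    lo, hi = clips_per_patient_range
    rows, specs = [], {}
    for p in range(n_patients):
        patient_id = f"P{p:04d}"
        patient_class = "B" if rng.random() < class_mix else "A"
        n_clips = int(rng.integers(lo, hi + 1))
        for c in range(n_clips):
            clip_id = f"{patient_id}C{c:02d}"
            n_frames = int(rng.integers(n_frames_range[0], n_frames_range[1] + 1))
            if patient_class == "B":
                het = rng.random() < heterogeneous_fraction
                homogeneity = "heterogeneous" if het else "homogeneous"
                severity = str(rng.choice(["mild", "moderate", "severe"]))
            else:
                homogeneity = "homogeneous"
                severity = "none"
            labels = make_frame_labels(n_frames, patient_class, homogeneity, rng)
            spec = ClipSpec(
                patient_id=patient_id,
                clip_id=clip_id,
                clip_label=patient_class,
                severity=severity,
                homogeneity=homogeneity,
                n_frames=n_frames,
                frame_labels=labels,
            )
            batch = 0
            if homogeneity == "homogeneous" and rng.random() < late_batch_fraction:
                batch = 1
            specs[clip_id] = spec
            rows.append(Clip(spec, []).manifest_row(batch=batch))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return Cohort(cfg=cfg, manifest=manifest, specs=specs)


def simulate_frame_probabilities(
    frame_labels,
    p_b: float = 0.95,
    p_a: float = 0.05,
    noise: float = 0.03,
    spike_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ground-truth-driven per-frame B-line probabilities.

    Emulates a well-calibrated frame classifier: B frames score near
    ``p_b``, A frames near ``p_a``, with optional isolated false-positive
    spikes on A frames at ``spike_rate``. Used to study the clip decision
    rule in isolation from any trained model.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    labels = np.asarray(frame_labels)
    p = np.where(labels == "B", p_b, p_a) + noise * rng.standard_normal(labels.shape)
    if spike_rate > 0:
        spikes = (labels == "A") & (rng.random(labels.shape) < spike_rate)
        p[spikes] = p_b + noise * rng.standard_normal(int(spikes.sum()))
    return np.clip(p, 0.0, 1.0)
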