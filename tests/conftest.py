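import dataclasses

import numpy as np
import pytest

import lus_abline as la


@pytest.fixture(scope="session")
def cfg128() -> la.PhantomConfig:
    return la.PhantomConfig()


@pytest.fixture(scope="session")
def cfg64() -> la.PhantomConfig:
    # narrower rays so every severity grade is realizable at 64x64
    return la.PhantomConfig(image_height=64, image_width=64, b_line_width=3.0)


def ray_energy_score(pixels: np.ndarray, cfg: la.PhantomConfig) -> float:
    """Hand-written B-line oracle, independent of the classifier.

    Bins the region below the pleural line by beam angle and returns
    the peak of the angular intensity profile over its median: B-line
    rays concentrate energy at their angles, while A-line
    reverberations spread evenly across the sector.
    """
    r, theta = cfg.polar()
    mask = cfg.sector_mask()
    depth = r - cfg.near_radius
    sel = mask & (depth > cfg.pleural_depth + 4)
    half = np.deg2rad(cfg.sector_angle / 2)
    bins = np.linspace(-half, half, 61)
    idx = np.digitize(theta[sel], bins)
    vals = pixels[sel]
    prof = np.array(
        [vals[idx == i].mean() if (idx == i).any() else 0.0 for i in range(1, 61)]
    )
    return float(prof.max() - np.median(prof))


RAY_SCORE_THRESHOLD = 0.08  # between A-frame max and B-frame min profiles


def oracle_label(pixels: np.ndarray, cfg: la.PhantomConfig) -> str:
    return "B" if ray_energy_score(pixels, cfg) > RAY_SCORE_THRESHOLD else "A"


def labelled_frames(cfg: la.PhantomConfig, n: int, seed: int = 0):
    """Balanced stack of A/B frames across severities, with labels."""
    rng = np.random.default_rng(seed)
    counts = {"mild": 2, "moderate": 4, "severe": 7}
    X, y, frames = [], [], []
    for i in range(n):
        lab = "B" if i % 2 else "A"
        c = dataclasses.replace(cfg, b_line_count=counts[["mild", "moderate", "severe"][i % 3]])
        f = la.generate_frame(c, lab, rng=int(rng.integers(2**31)))
        X.append(f.pixels)
        y.append(1 if lab == "B" else 0)
        frames.append(f)
    return np.stack(X), np.array(y), frames


@pytest.fixture(scope="session")
def trained_model_64(cfg64):
    """A frame classifier trained to convergence on 64x64 phantom frames."""
    X, y, _ = labelled_frames(cfg64, 96, seed=11)
    Xv, yv, _ = labelled_frames(cfg64, 24, seed=12)
    model = la.build_model(input_shape=(64, 64), seed=0)
    history = la.train(
        model,
        X,
        y,
        Xv,
        yv,
        la.TrainConfig(epochs=6, batch_size=8, learning_rate=2e-3, seed=0),
    )
    return model, history
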