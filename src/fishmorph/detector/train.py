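"""Training and inference loops for the heatmap detector.

Full-batch Adam on the summed per-stack heatmap MSE.  The desk-scale recipe
(a few hundred steps on a few dozen 64x64 rasterized views) is meant to
overfit its training set — a functional sanity regime demonstrating that the
architecture can localize the skeleton landmarks — not to reproduce
full-resolution camera training.
"""

from __future__ import annotations

import numpy as np

from .autodiff import mse
from .heatmaps import decode_heatmaps, encode_heatmaps
from .model import Adam, DetectorConfig, StackedHourglass

__all__ = ["TrainingError", "train", "detect"]


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""


def train(
    model: StackedHourglass,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: DetectorConfig | None = None,
    seed: int = 0,
    steps: int = 300,
    lr_decay: float = 0.3,
    lr_decay_at: float = 0.7,
) -> list[float]:
    """Fit the model to (image, keypoints) pairs; returns the loss trace.

    ``dataset`` holds grayscale images (S, S) in [0, 1] with their keypoint
    arrays (K, 2) in input pixels.  Training is deterministic given the
    dataset and model: full batch, no dropout, no shuffling (``seed`` is
    accepted for interface symmetry and reserved for future stochastic
    augmentation).  ``steps=0`` leaves the model untouched.  The learning
    rate starts at the config value and is multiplied by ``lr_decay`` after
    the ``lr_decay_at`` fraction of steps (the late low-rate phase settles
    the heatmap peaks onto their cells).
    """
    if not dataset:
        raise TrainingError("empty training dataset")
    cfg = config or model.config
    images = np.stack([img for img, _ in dataset])[:, None, :, :]
    targets = np.stack([encode_heatmaps(kps, cfg) for _, kps in dataset]).astype(np.float32)

    opt = Adam(model.params(), lr=cfg.learning_rate)
    trace: list[float] = []
    for step in range(steps):
        if step == int(steps * lr_decay_at):
            opt.lr = cfg.learning_rate * lr_decay
        outputs = model(images)
        loss = None
        for hm in outputs:
            term = mse(hm, targets)
            loss = term if loss is None else _add_scalars(loss, term)
        value = float(loss.data) / len(outputs)
        if not np.isfinite(value):
            raise TrainingError(f"training diverged at step {len(trace)}: loss={value}")
        trace.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return trace


def _add_scalars(a, b):
    from .autodiff import add

    return add(a, b)


def heatmap_loss(model: StackedHourglass, dataset: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Current mean per-stack heatmap MSE of the model on a dataset."""
    cfg = model.config
    images = np.stack([img for img, _ in dataset])[:, None, :, :]
    targets = np.stack([encode_heatmaps(kps, cfg) for _, kps in dataset]).astype(np.float32)
    outputs = model(images)
    return float(np.mean([np.mean((hm.data - targets) ** 2) for hm in outputs]))


def detect(model: StackedHourglass, image: np.ndarray, config: DetectorConfig | None = None) -> np.ndarray:
    """Keypoints (K, 2) in input pixels from one grayscale image (S, S)."""
    cfg = config or model.config
    heatmaps = model.predict(image[None, None, :, :])[0]
    return decode_heatmaps(heatmaps, cfg)


def make_detection_dataset(
    n: int, view: str, seed: int, input_size: int = 64
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rasterized synthetic views paired with their true keypoint pixels.

    Each item is one random specimen seen by the desk-scale camera; the
    keypoints are the exact projections of the view's annotated landmarks
    (10 side, 9 top), in input pixels.
    """
    from ..synthetic import desk_camera, random_specimen, rasterize

    camera = desk_camera(view, size=input_size)
    symbols = [f"S{i}" for i in range(1, 11)] if view == "side" else [f"T{i}" for i in range(1, 10)]
    dataset = []
    for i in range(n):
        spec3d = random_specimen(seed + i)
        image = rasterize(spec3d, camera, seed=seed + i)
        kps = np.array([camera.project_point(spec3d.landmarks3d[s]) for s in symbols])
        dataset.append((image, kps))
    return dataset
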