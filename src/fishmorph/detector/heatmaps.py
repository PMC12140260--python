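"""Gaussian heatmap encoding and argmax decoding of keypoints.

A keypoint at input-resolution position (x, y) is encoded as an unnormalized
Gaussian bump (peak value 1.0) centred at (x, y) / upscale_factor on the
heatmap grid.  Decoding is the per-map argmax multiplied back by the upscale
factor — deliberately without sub-pixel refinement, so the quantization
error is bounded by one heatmap cell (upscale_factor pixels) per axis; with
the reference full-resolution setup (128x128 maps upscaled x16) that bound
is the dominant systematic error of the automated measurements.

Ties in the argmax resolve to the lowest row-major index; an all-zero map
decodes to the heatmap centre with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import DetectorConfig

__all__ = ["EncodeError", "encode_heatmaps", "decode_heatmaps", "letterbox", "unletterbox"]

logger = logging.getLogger(__name__)


class EncodeError(ValueError):
    """Raised when a keypoint cannot be encoded (outside input bounds)."""


def encode_heatmaps(keypoints: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Encode keypoints (K, 2) in input pixels into heatmaps (K, H, H).

    Each map is ``exp(-((u-cx)^2 + (v-cy)^2) / (2 sigma^2))`` on the heatmap
    grid, with the centre at the keypoint scaled into heatmap coordinates.
    The peak value is 1.0 when the centre falls on a grid node.
    """
    kps = np.asarray(keypoints, dtype=float)
    if kps.ndim != 2 or kps.shape[1] != 2:
        raise EncodeError(f"keypoints must be (K, 2), got {kps.shape}")
    s = config.input_size
    if np.any(kps < 0) or np.any(kps > s) or not np.all(np.isfinite(kps)):
        raise EncodeError(f"keypoints outside input bounds [0, {s}]")
    h = config.heatmap_size
    centers = kps / config.upscale_factor
    grid = np.arange(h, dtype=float)
    u = grid[None, None, :]  # columns (x)
    v = grid[None, :, None]  # rows (y)
    cx = centers[:, 0][:, None, None]
    cy = centers[:, 1][:, None, None]
    sq = (u - cx) ** 2 + (v - cy) ** 2
    return np.exp(-sq / (2.0 * config.gaussian_sigma ** 2))


def decode_heatmaps(
    stack: np.ndarray, config: DetectorConfig, refine: bool = False
) -> np.ndarray:
    """Decode heatmaps (K, H, H) to keypoints (K, 2) in input pixels.

    Per-map argmax (row-major first on ties) times the upscale factor.
    With ``refine=True`` (off by default, so the quantization-error
    analysis of plain argmax decoding applies) the peak is adjusted by a
    per-axis parabolic fit through the argmax and its two neighbours,
    clamped to half a cell.
    """
    maps = np.asarray(stack, dtype=float)
    if maps.ndim != 3 or maps.shape[1:] != (config.heatmap_size,) * 2:
        raise ValueError(f"expected (K, {config.heatmap_size}, {config.heatmap_size}), got {maps.shape}")
    f = config.upscale_factor
    h = config.heatmap_size
    out = np.empty((maps.shape[0], 2))
    for k, m in enumerate(maps):
        if np.all(m == 0):
            logger.warning("heatmap %d is all-zero; decoding to the map centre", k)
            row = col = h // 2
        else:
            row, col = np.unravel_index(int(np.argmax(m)), m.shape)
        x, y = float(col), float(row)
        if refine:
            if 0 < col < h - 1:
                x += _parabolic_offset(m[row, col - 1], m[row, col], m[row, col + 1])
            if 0 < row < h - 1:
                y += _parabolic_offset(m[row - 1, col], m[row, col], m[row + 1, col])
        out[k] = (x * f, y * f)
    return out


def _parabolic_offset(left: float, centre: float, right: float) -> float:
    denom = 2.0 * centre - left - right
    if denom <= 0:
        return 0.0
    return float(np.clip(0.5 * (right - left) / denom, -0.5, 0.5))


def letterbox(image: np.ndarray, size: int) -> tuple[np.ndarray, dict]:
    """Pad-and-scale a rectangular grayscale image to ``size`` x ``size``.

    Returns the square image plus the transform record
    ``{"scale", "pad_x", "pad_y"}`` needed to map detected keypoints back to
    original pixel coordinates via :func:`unletterbox`.
    """
    from skimage.transform import resize

    h, w = image.shape
    scale = size / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    resized = resize(image, (nh, nw), preserve_range=True, anti_aliasing=True)
    pad_y, pad_x = (size - nh) // 2, (size - nw) // 2
    out = np.zeros((size, size), dtype=image.dtype)
    out[pad_y : pad_y + nh, pad_x : pad_x + nw] = resized
    return out, {"scale": scale, "pad_x": pad_x, "pad_y": pad_y}


def unletterbox(keypoints: np.ndarray, transform: dict) -> np.ndarray:
    """Map keypoints detected on a letterboxed image back to original pixels."""
    kps = np.asarray(keypoints, dtype=float).copy()
    kps[:, 0] = (kps[:, 0] - transform["pad_x"]) / transform["scale"]
    kps[:, 1] = (kps[:, 1] - transform["pad_y"]) / transform["scale"]
    return kps
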