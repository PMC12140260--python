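"""Pixel-to-metric calibration from a ruler of known length in each view.

Each camera is calibrated independently: a ruler of known physical length is
photographed in the view, its pixel length measured, and the ratio gives the
view's scale in cm per pixel.  Every measurement formula multiplies a pixel
distance by this scale to obtain centimetres, so the scale is stored as
truth/pixel (cm per px) — the only dimensionally consistent direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CalibrationError", "ScaleParams", "compute_scale", "calibrate_views"]


class CalibrationError(ValueError):
    """Raised for non-positive or non-finite ruler readings or scales."""


@dataclass(frozen=True)
class ScaleParams:
    """cm-per-pixel conversion factors for the two views.

    ``side_scale`` converts side-view (lateral camera) pixel distances to cm;
    ``top_scale`` does the same for the top-view (dorsal camera).
    """

    side_scale: float
    top_scale: float

    def __post_init__(self) -> None:
        for name in ("side_scale", "top_scale"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise CalibrationError(f"{name} must be positive and finite, got {v!r}")


def compute_scale(ruler_pixel_length: float, ruler_true_length: float) -> float:
    """Scale of one view, in cm per pixel.

    Parameters
    ----------
    ruler_pixel_length : float
        Measured length of the reference ruler in the image, in pixels.
    ruler_true_length : float
        Physical length of the ruler, in cm.
    """
    for name, v in (
        ("ruler_pixel_length", ruler_pixel_length),
        ("ruler_true_length", ruler_true_length),
    ):
        if not (math.isfinite(v) and v > 0):
            raise CalibrationError(f"{name} must be positive and finite, got {v!r}")
    return ruler_true_length / ruler_pixel_length


def calibrate_views(
    side_ruler: tuple[float, float], top_ruler: tuple[float, float]
) -> ScaleParams:
    """Calibrate both views from per-view ``(pixel_length, true_length_cm)``."""
    return ScaleParams(
        side_scale=compute_scale(*side_ruler),
        top_scale=compute_scale(*top_ruler),
    )
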