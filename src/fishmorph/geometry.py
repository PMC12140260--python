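"""Planar vector primitives and the dual-view 3D length reconstruction.

All morphometric formulas reduce to five primitives on image-plane points:
Euclidean distance, point-to-point vectors, the absolute cosine of a vector
against the horizontal image axis, the magnitude of a scalar projection, and
the proportion of one segment within a polyline.  On top of these sits the
single genuinely three-dimensional step of the pipeline:
:func:`reconstruct_3d_length`, which recovers the true length of a segment in
3D space from its projected length in one camera plane plus its inclination
cosines in both orthogonal views.

Conventions
-----------
* Image coordinates are continuous (sub-pixel), origin top-left, x rightward,
  y downward.  No rounding happens anywhere in this module.
* The "horizontal axis" shared by both views is the image x axis, which both
  cameras see as the fish's snout-to-tail direction.
* Cosines are returned as absolute values: every downstream use feeds them
  into :func:`reconstruct_3d_length`, where only ``cos**2`` and ``sin**2``
  survive, so the absolute value removes sign ambiguity for vectors that
  happen to point tailward.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

__all__ = [
    "Point2D",
    "Vector2D",
    "DegenerateGeometryError",
    "COS_TOP_EPS",
    "dist",
    "vec",
    "axis_cosine",
    "scalar_projection",
    "reconstruct_3d_length",
    "polyline_proportions",
    "polyline_proportion",
]

#: Guard on the top-view cosine: below this the reconstruction divides by a
#: near-zero quantity and the recovered length is unbounded (the segment is
#: viewed almost end-on by the top camera).
COS_TOP_EPS = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when a geometric primitive is undefined for its inputs
    (zero-length vector, collapsed polyline, near-perpendicular view)."""


class Point2D(NamedTuple):
    """A continuous image-plane point in pixels (x rightward, y downward)."""

    x: float
    y: float


class Vector2D(NamedTuple):
    """A displacement in the image plane, in pixels."""

    dx: float
    dy: float

    @property
    def norm(self) -> float:
        return math.hypot(self.dx, self.dy)


def dist(a: Point2D, b: Point2D) -> float:
    """Euclidean distance between two image points, in pixels."""
    return math.hypot(b[0] - a[0], b[1] - a[1])


def vec(a: Point2D, b: Point2D) -> Vector2D:
    """Displacement vector from ``a`` to ``b``."""
    return Vector2D(b[0] - a[0], b[1] - a[1])


def axis_cosine(v: Vector2D) -> float:
    """Absolute cosine of the angle between ``v`` and the horizontal axis.

    Returns ``|dx| / |v|`` in [0, 1].  A horizontal vector gives 1, a
    vertical one gives 0.

    Raises
    ------
    DegenerateGeometryError
        If ``v`` has zero length (the angle is undefined).
    """
    n = math.hypot(v[0], v[1])
    if n == 0.0:
        raise DegenerateGeometryError("axis cosine of a zero-length vector")
    return abs(v[0]) / n


def scalar_projection(u: Vector2D, onto: Vector2D) -> float:
    """Magnitude of the scalar projection of ``u`` onto ``onto``, in pixels.

    Returns ``|u . onto| / |onto|``.  The magnitude (rather than the signed
    projection) is used because the tail-length rule compares projections as
    lengths and takes a minimum; a signed value would corrupt that comparison
    for a backward-pointing tail point.
    """
    n = math.hypot(onto[0], onto[1])
    if n == 0.0:
        raise DegenerateGeometryError("projection onto a zero-length vector")
    return abs(u[0] * onto[0] + u[1] * onto[1]) / n


def reconstruct_3d_length(proj_len: float, cos_side: float, cos_top: float) -> float:
    """Recover a segment's true 3D length from one projection and two cosines.

    The segment OA lives in 3D; the side camera sees its projection OA' (of
    length ``proj_len``, already converted to cm) in the vertical plane, at
    angle alpha to the horizontal axis; the top camera sees its projection in
    the horizontal plane at angle beta to the same axis.  With
    ``sin(alpha) = sqrt(1 - cos_side**2)`` the true length is::

        |OA| = sqrt( (proj_len * cos_side / cos_top)**2
                     + (proj_len * sin(alpha))**2 )

    The horizontal component of OA' (``proj_len * cos_side``) lies along the
    shared axis; dividing by ``cos_top`` restores the in-horizontal-plane
    length of OA, whose vertical component ``proj_len * sin(alpha)`` is seen
    undistorted by the side camera.  The result is exact for any segment, is
    always >= ``proj_len``, and equals it when ``cos_top == 1``.

    Parameters
    ----------
    proj_len : float
        Length of the side-view projection, in cm (or any length unit; the
        output shares it).  Must be >= 0.
    cos_side : float
        Absolute cosine of the side-view projection against the horizontal
        axis, in [0, 1].
    cos_top : float
        Absolute cosine of the top-view projection against the same axis.
        Must satisfy ``|cos_top| >= COS_TOP_EPS``.

    Raises
    ------
    DegenerateGeometryError
        If ``|cos_top| < COS_TOP_EPS`` (the top camera views the segment
        nearly end-on and its length is unrecoverable), or on invalid inputs.
    """
    if proj_len < 0:
        raise DegenerateGeometryError(f"negative projected length {proj_len!r}")
    ca = abs(cos_side)
    cb = abs(cos_top)
    if ca > 1.0 + 1e-9:
        raise DegenerateGeometryError(f"side cosine {cos_side!r} outside [-1, 1]")
    ca = min(ca, 1.0)
    if cb < COS_TOP_EPS:
        raise DegenerateGeometryError(
            f"top-view cosine {cos_top!r} below {COS_TOP_EPS}: "
            "segment nearly perpendicular to the shared axis in the top view"
        )
    sin_a = math.sqrt(max(0.0, 1.0 - ca * ca))
    return math.hypot(proj_len * ca / cb, proj_len * sin_a)


def polyline_proportions(vertices: Sequence[Point2D]) -> list[float]:
    """Fraction of the total polyline length carried by each segment.

    ``vertices`` are the ordered polyline vertices (``n`` vertices define
    ``n - 1`` segments).  The proportions are non-negative and sum to 1.

    Raises
    ------
    DegenerateGeometryError
        If fewer than two vertices are given or the polyline has zero total
        length.
    """
    if len(vertices) < 2:
        raise DegenerateGeometryError("a polyline needs at least two vertices")
    lengths = [dist(a, b) for a, b in zip(vertices[:-1], vertices[1:])]
    total = sum(lengths)
    if total == 0.0:
        raise DegenerateGeometryError("polyline has zero total length")
    return [l / total for l in lengths]


def polyline_proportion(seg_index: int, vertices: Sequence[Point2D]) -> float:
    """Proportion of segment ``seg_index`` (0-based) within the polyline."""
    return polyline_proportions(vertices)[seg_index]
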