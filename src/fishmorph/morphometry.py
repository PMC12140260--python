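"""The seven phenotypic measurements from one dual-view annotation.

Three traits are purely planar (a single-view pixel distance times that
view's scale): body thickness BT from the top view, body height BH and
tail-handle height THH from the side view.  The remaining four — head length
HL, body length BL, full length FL and tail-handle width THW — correct for
out-of-plane posture with the dual-view 3D reconstruction: a side-view length
is combined with its side inclination cosine and the matching top-view
segment's inclination cosine.

Body length follows the fish's curvature: the head segment (mouth S1 to
head-middle S11) is reconstructed directly, and the mid-body side-view chord
length (S11->S12 plus S12->S8) is distributed over the three top-view
polyline segments T10->T11->T7->T8 in proportion to their top-view lengths,
each share reconstructed with the single side chord cosine of S12->S11 and
that segment's own top cosine.  Full length adds the tail: the shorter of the
two tail-fin tips' (S9, S10) projections onto the body axis S12->S11, with
the chosen tip's side cosine and the top tail segment T8->T9 cosine.
Tail-handle width sums the axis projections of S12->S5 and S8->S12 and
reconstructs with the T8->T7 top cosine.

All outputs are in cm; full length always >= body length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .geometry import (
    DegenerateGeometryError,
    axis_cosine,
    dist,
    polyline_proportions,
    reconstruct_3d_length,
    scalar_projection,
    vec,
)
from .skeleton import AnnotatedSpecimen, validate_annotation

__all__ = [
    "PhenotypeRecord",
    "MeasurementError",
    "TRAIT_NAMES",
    "body_thickness",
    "body_height",
    "tail_handle_height",
    "head_length",
    "body_length",
    "full_length",
    "tail_handle_width",
    "measure",
    "records_to_frame",
    "write_measurements_csv",
]

#: Column order used in every tabular output.
TRAIT_NAMES = ("FL", "BL", "BH", "BT", "HL", "THH", "THW")


class MeasurementError(ValueError):
    """A measurement failed on a specimen; names the failing trait."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """The seven measurements of one specimen, in cm."""

    specimen_id: str
    full_length: float
    body_length: float
    body_height: float
    body_thickness: float
    head_length: float
    tail_handle_height: float
    tail_handle_width: float

    def as_dict(self) -> dict[str, float]:
        """Trait values keyed by their conventional abbreviations."""
        return {
            "FL": self.full_length,
            "BL": self.body_length,
            "BH": self.body_height,
            "BT": self.body_thickness,
            "HL": self.head_length,
            "THH": self.tail_handle_height,
            "THW": self.tail_handle_width,
        }


def body_thickness(spec: AnnotatedSpecimen) -> float:
    """BT: distance between the pectoral-fin points T2, T3, top view (cm)."""
    return dist(spec.top.t2, spec.top.t3) * spec.scales.top_scale


def body_height(spec: AnnotatedSpecimen) -> float:
    """BH: distance between head-up S3 and head-down S4, side view (cm)."""
    return dist(spec.side.s3, spec.side.s4) * spec.scales.side_scale


def tail_handle_height(spec: AnnotatedSpecimen) -> float:
    """THH: distance between small-up S6 and small-down S7, side view (cm)."""
    return dist(spec.side.s6, spec.side.s7) * spec.scales.side_scale


def head_length(spec: AnnotatedSpecimen) -> float:
    """HL: mouth-to-gill segment S1->S2 reconstructed in 3D (cm).

    Side length and cosine come from S1->S2; the top-view inclination is taken
    from the head chord T1->T10 (mouth to fin-middle), the top view's proxy
    for the head direction.
    """
    d = spec.derived()
    side_len = dist(spec.side.s1, spec.side.s2) * spec.scales.side_scale
    if side_len == 0.0:
        return 0.0
    return reconstruct_3d_length(
        side_len,
        axis_cosine(vec(spec.side.s1, spec.side.s2)),
        axis_cosine(vec(spec.top.t1, d.t10_fin_middle)),
    )


def body_length(spec: AnnotatedSpecimen) -> float:
    """BL: curvature-following snout-to-caudal-base length (cm)."""
    d = spec.derived()
    s = spec.side
    ls = spec.scales.side_scale

    # Head segment S1 -> S11, top direction from T1 -> T10.
    l_hm = reconstruct_3d_length(
        dist(s.s1, d.s11_head_middle) * ls,
        axis_cosine(vec(s.s1, d.s11_head_middle)),
        axis_cosine(vec(spec.top.t1, d.t10_fin_middle)),
    )

    # Mid-body side chord length, split over the top-view polyline.
    tmp = (dist(d.s11_head_middle, d.s12_small_middle) + dist(s.s8, d.s12_small_middle)) * ls
    polyline = (d.t10_fin_middle, d.t11_middle_middle, spec.top.t7, spec.top.t8)
    props = polyline_proportions(polyline)
    cos_side_mid = axis_cosine(vec(d.s12_small_middle, d.s11_head_middle))
    total = l_hm
    for prop, (a, b) in zip(props, zip(polyline[:-1], polyline[1:])):
        total += reconstruct_3d_length(tmp * prop, cos_side_mid, axis_cosine(vec(b, a)))
    return total


def _tail_projection_px(spec: AnnotatedSpecimen) -> tuple[float, float]:
    """Tail pixel length (min projection) and the chosen tip's side cosine.

    Both tail-fin tips S9 and S10 are projected (via the vectors tip->S8)
    onto the body axis S12->S11; the shorter projection is the tail length
    and that tip's own axis cosine is carried into the reconstruction.  Ties
    resolve to S9 (the upper tip), deterministically.
    """
    d = spec.derived()
    s = spec.side
    axis = vec(d.s12_small_middle, d.s11_head_middle)
    p9 = scalar_projection(vec(s.s9, s.s8), axis)
    p10 = scalar_projection(vec(s.s10, s.s8), axis)
    if p9 <= p10:
        return p9, axis_cosine(vec(s.s9, s.s8))
    return p10, axis_cosine(vec(s.s10, s.s8))


def full_length(spec: AnnotatedSpecimen) -> float:
    """FL: body length plus the reconstructed tail-fin length (cm)."""
    tail_px, cos_side_tail = _tail_projection_px(spec)
    tail = reconstruct_3d_length(
        tail_px * spec.scales.side_scale,
        cos_side_tail,
        axis_cosine(vec(spec.top.t8, spec.top.t9)),
    )
    return body_length(spec) + tail


def tail_handle_width(spec: AnnotatedSpecimen) -> float:
    """THW: longitudinal caudal-peduncle extent (cm).

    The projections of S12->S5 (to the anal-fin inflection) and S8->S12 onto
    the body axis S12->S11 are summed in side-view pixels, scaled, and
    reconstructed with the S12->S11 side cosine and the T8->T7 top cosine.
    """
    d = spec.derived()
    s = spec.side
    axis = vec(d.s12_small_middle, d.s11_head_middle)
    span_px = scalar_projection(vec(d.s12_small_middle, s.s5), axis) + scalar_projection(
        vec(s.s8, d.s12_small_middle), axis
    )
    if span_px == 0.0:
        return 0.0
    return reconstruct_3d_length(
        span_px * spec.scales.side_scale,
        axis_cosine(axis),
        axis_cosine(vec(spec.top.t8, spec.top.t7)),
    )


_MEASUREMENTS = (
    ("full_length", full_length),
    ("body_length", body_length),
    ("body_height", body_height),
    ("body_thickness", body_thickness),
    ("head_length", head_length),
    ("tail_handle_height", tail_handle_height),
    ("tail_handle_width", tail_handle_width),
)


def measure(spec: AnnotatedSpecimen, validate: bool = True) -> PhenotypeRecord:
    """Apply all seven measurements to one specimen.

    Raises
    ------
    MeasurementError
        If validation finds problems, or a measurement hits degenerate
        geometry; the message names the failing trait or findings.
    """
    if validate:
        findings = validate_annotation(spec)
        if findings:
            raise MeasurementError(
                f"specimen '{spec.specimen_id}' failed validation: " + "; ".join(findings)
            )
    values: dict[str, float] = {}
    for name, fn in _MEASUREMENTS:
        try:
            values[name] = fn(spec)
        except DegenerateGeometryError as e:
            raise MeasurementError(
                f"specimen '{spec.specimen_id}': {name} failed: {e}"
            ) from e
    return PhenotypeRecord(specimen_id=spec.specimen_id, **values)


def records_to_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Tabulate records as one row per specimen, columns specimen_id + traits."""
    rows = [{"specimen_id": r.specimen_id, **r.as_dict()} for r in records]
    return pd.DataFrame(rows, columns=["specimen_id", *TRAIT_NAMES])


def write_measurements_csv(
    records: list[PhenotypeRecord],
    path,
    precision: int = 3,
    header_comment: str | None = None,
) -> None:
    """Write measurements CSV (cm, fixed decimal places, default 3)."""
    frame = records_to_frame(records)
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    frame.to_csv(buf, index=False, float_format=f"%.{precision}f")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
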