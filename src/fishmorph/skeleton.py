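"""Keypoint skeletons for the two orthogonal fish views.

The side (lateral) view carries ten named landmarks S1..S10 and the top
(dorsal) view nine landmarks T1..T9, placed on anatomically defined points of
the body outline (mouth, gill margin, dorsal/ventral profile inflections,
caudal-peduncle extremes, tail-fin tips).  Four pseudo-landmarks are derived
as midpoints of annotated pairs: T10 (fin-middle), S11 (head-middle),
S12 (small-middle) and T11 (middle-middle); these define the body axis and
segment chain every length measurement is built on.

Canonical orientation is head-left: the mouth has the smaller image-x in both
views.  Annotations violating this are flipped horizontally on load (with a
logged warning) rather than rejected.  Annotation completeness is mandatory
for measurement: every formula consumes specific named points, so specimens
with missing landmarks fail validation and are excluded.

The on-disk format is a small versioned JSON document (see
:class:`AnnotationDocument`); label strings follow the anatomical point names
("side-head", ..., "top-tail").
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field

from .calibration import ScaleParams
from .geometry import Point2D

__all__ = [
    "SIDE_LABELS",
    "TOP_LABELS",
    "SideKeypointSet",
    "TopKeypointSet",
    "DerivedPoints",
    "AnnotatedSpecimen",
    "AnnotationError",
    "derive_midpoints",
    "validate_annotation",
    "AnnotationDocument",
    "load_annotation",
    "save_annotation",
    "specimen_to_document",
]

logger = logging.getLogger(__name__)

#: Side-view label names, in symbol order S1..S10.
SIDE_LABELS: tuple[str, ...] = (
    "side-head",    # S1  mouth
    "head-fin",     # S2  gill point farthest from the mouth
    "head-up",      # S3  dorsal-profile inflection at the dorsal fin
    "head-down",    # S4  ventral point below head-up
    "front-small",  # S5  anal-fin / body-profile inflection
    "small-up",     # S6  upper point of the narrowest caudal peduncle
    "small-down",   # S7  lower point of the narrowest caudal peduncle
    "side-tail",    # S8  body/tail junction on the body axis
    "tail-up",      # S9  upper tail-fin tip
    "tail-down",    # S10 lower tail-fin tip
)

#: Top-view label names, in symbol order T1..T9.
TOP_LABELS: tuple[str, ...] = (
    "top-head",      # T1 mouth
    "fin-right",     # T2 right pectoral-fin inflection
    "fin-left",      # T3 left pectoral-fin inflection
    "fin-up",        # T4 dorsal counterpart of head-up (carried, unused downstream)
    "middle-right",  # T5 right ventral-fin inflection
    "middle-left",   # T6 left ventral-fin inflection
    "middle",        # T7 second-dorsal-fin inflection
    "small-tail",    # T8 narrowest caudal peduncle
    "top-tail",      # T9 longest tail-fin point
)


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations (missing labels, bad JSON)."""


def _as_point(p) -> Point2D:
    return Point2D(float(p[0]), float(p[1]))


@dataclass(frozen=True)
class SideKeypointSet:
    """The ten side-view landmarks, S1..S10."""

    s1: Point2D
    s2: Point2D
    s3: Point2D
    s4: Point2D
    s5: Point2D
    s6: Point2D
    s7: Point2D
    s8: Point2D
    s9: Point2D
    s10: Point2D

    _FIELDS = tuple(f"s{i}" for i in range(1, 11))

    @classmethod
    def from_labels(cls, points: Mapping[str, tuple[float, float]]) -> "SideKeypointSet":
        missing = [l for l in SIDE_LABELS if l not in points]
        if missing:
            raise AnnotationError(f"side view missing keypoints: {missing}")
        return cls(*(_as_point(points[l]) for l in SIDE_LABELS))

    def to_labels(self) -> dict[str, Point2D]:
        return {l: getattr(self, f) for l, f in zip(SIDE_LABELS, self._FIELDS)}

    def points(self) -> list[Point2D]:
        return [getattr(self, f) for f in self._FIELDS]


@dataclass(frozen=True)
class TopKeypointSet:
    """The nine top-view landmarks, T1..T9."""

    t1: Point2D
    t2: Point2D
    t3: Point2D
    t4: Point2D
    t5: Point2D
    t6: Point2D
    t7: Point2D
    t8: Point2D
    t9: Point2D

    _FIELDS = tuple(f"t{i}" for i in range(1, 10))

    @classmethod
    def from_labels(cls, points: Mapping[str, tuple[float, float]]) -> "TopKeypointSet":
        missing = [l for l in TOP_LABELS if l not in points]
        if missing:
            raise AnnotationError(f"top view missing keypoints: {missing}")
        return cls(*(_as_point(points[l]) for l in TOP_LABELS))

    def to_labels(self) -> dict[str, Point2D]:
        return {l: getattr(self, f) for l, f in zip(TOP_LABELS, self._FIELDS)}

    def points(self) -> list[Point2D]:
        return [getattr(self, f) for f in self._FIELDS]


@dataclass(frozen=True)
class DerivedPoints:
    """The four midpoint pseudo-landmarks T10, S11, S12, T11."""

    t10_fin_middle: Point2D
    s11_head_middle: Point2D
    s12_small_middle: Point2D
    t11_middle_middle: Point2D


def _midpoint(a: Point2D, b: Point2D) -> Point2D:
    return Point2D((a.x + b.x) / 2.0, (a.y + b.y) / 2.0)


def derive_midpoints(side: SideKeypointSet, top: TopKeypointSet) -> DerivedPoints:
    """Compute the four derived midpoints from their annotated parents.

    T10 = midpoint(fin-left, fin-right); S11 = midpoint(head-up, head-down);
    S12 = midpoint(small-up, small-down); T11 = midpoint(middle-left,
    middle-right).  Each is the exact componentwise arithmetic midpoint.
    """
    return DerivedPoints(
        t10_fin_middle=_midpoint(top.t3, top.t2),
        s11_head_middle=_midpoint(side.s3, side.s4),
        s12_small_middle=_midpoint(side.s6, side.s7),
        t11_middle_middle=_midpoint(top.t6, top.t5),
    )


@dataclass(frozen=True)
class AnnotatedSpecimen:
    """One fish's full annotation: both views plus per-view scales."""

    specimen_id: str
    side: SideKeypointSet
    top: TopKeypointSet
    scales: ScaleParams
    side_image_size: tuple[int, int] | None = None  # (width, height) px
    top_image_size: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def derived(self) -> DerivedPoints:
        return derive_midpoints(self.side, self.top)


def _check_view(
    labels: tuple[str, ...],
    points: Mapping[str, Point2D],
    image_size: tuple[int, int] | None,
    view: str,
    findings: list[str],
) -> None:
    for label in labels:
        p = points.get(label)
        if p is None:
            findings.append(f"{view}: keypoint '{label}' is missing")
            continue
        if not (math.isfinite(p.x) and math.isfinite(p.y)):
            findings.append(f"{view}: keypoint '{label}' is not finite: {p}")
        elif image_size is not None:
            w, h = image_size
            if not (0 <= p.x <= w and 0 <= p.y <= h):
                findings.append(
                    f"{view}: keypoint '{label}' at ({p.x:g}, {p.y:g}) "
                    f"outside image bounds {w}x{h}"
                )


def validate_annotation(spec: AnnotatedSpecimen) -> list[str]:
    """Check a specimen for completeness, finiteness, bounds and orientation.

    Returns one human-readable finding per violation; an empty list means the
    specimen is measurable.  Findings are diagnostics, not exceptions, so a
    batch run can report all problems of all specimens.
    """
    findings: list[str] = []
    _check_view(SIDE_LABELS, spec.side.to_labels(), spec.side_image_size, "side", findings)
    _check_view(TOP_LABELS, spec.top.to_labels(), spec.top_image_size, "top", findings)
    if spec.side.s1.x > spec.side.s8.x:
        findings.append("side: orientation not canonical (mouth right of tail; head must be left)")
    if spec.top.t1.x > spec.top.t9.x:
        findings.append("top: orientation not canonical (mouth right of tail; head must be left)")
    return findings


# ---------------------------------------------------------------------------
# Annotation JSON document (versioned on-disk schema)
# ---------------------------------------------------------------------------

class ViewAnnotation(BaseModel):
    """One view's block in the annotation document."""

    model_config = ConfigDict(extra="forbid")

    image_size: tuple[int, int] | None = None
    keypoints: dict[str, tuple[float, float]]


class ScalesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    side_cm_per_px: float = Field(gt=0)
    top_cm_per_px: float = Field(gt=0)


class AnnotationDocument(BaseModel):
    """Versioned JSON schema for one specimen's dual-view annotation."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    specimen_id: str
    side: ViewAnnotation
    top: ViewAnnotation
    scales: ScalesBlock | None = None
    metadata: dict = Field(default_factory=dict)


def _flip_view(
    points: dict[str, tuple[float, float]], image_size: tuple[int, int] | None
) -> dict[str, tuple[float, float]]:
    # Mirror about the image's vertical centreline when the width is known,
    # otherwise about the annotation's own bounding box.
    if image_size is not None:
        lo_hi = 0.0 + image_size[0]
    else:
        xs = [p[0] for p in points.values()]
        lo_hi = min(xs) + max(xs)
    return {l: (lo_hi - p[0], p[1]) for l, p in points.items()}


def document_to_specimen(
    doc: AnnotationDocument, scales: ScaleParams | None = None
) -> AnnotatedSpecimen:
    """Build an :class:`AnnotatedSpecimen` from a parsed document.

    ``scales`` overrides the document's embedded scales; one of the two must
    be present.  Non-canonical (head-right) views are flipped here, with a
    warning, before the keypoint sets are built.
    """
    if scales is None:
        if doc.scales is None:
            raise AnnotationError(
                f"specimen '{doc.specimen_id}': no scales embedded and none supplied"
            )
        scales = ScaleParams(doc.scales.side_cm_per_px, doc.scales.top_cm_per_px)

    side_pts = dict(doc.side.keypoints)
    top_pts = dict(doc.top.keypoints)
    if "side-head" in side_pts and "side-tail" in side_pts:
        if side_pts["side-head"][0] > side_pts["side-tail"][0]:
            logger.warning(
                "specimen %s: side view head-right; flipping to canonical head-left",
                doc.specimen_id,
            )
            side_pts = _flip_view(side_pts, doc.side.image_size)
    if "top-head" in top_pts and "top-tail" in top_pts:
        if top_pts["top-head"][0] > top_pts["top-tail"][0]:
            logger.warning(
                "specimen %s: top view head-right; flipping to canonical head-left",
                doc.specimen_id,
            )
            top_pts = _flip_view(top_pts, doc.top.image_size)

    return AnnotatedSpecimen(
        specimen_id=doc.specimen_id,
        side=SideKeypointSet.from_labels(side_pts),
        top=TopKeypointSet.from_labels(top_pts),
        scales=scales,
        side_image_size=doc.side.image_size,
        top_image_size=doc.top.image_size,
        metadata=dict(doc.metadata),
    )


def specimen_to_document(spec: AnnotatedSpecimen) -> AnnotationDocument:
    return AnnotationDocument(
        specimen_id=spec.specimen_id,
        side=ViewAnnotation(
            image_size=spec.side_image_size,
            keypoints={l: (p.x, p.y) for l, p in spec.side.to_labels().items()},
        ),
        top=ViewAnnotation(
            image_size=spec.top_image_size,
            keypoints={l: (p.x, p.y) for l, p in spec.top.to_labels().items()},
        ),
        scales=ScalesBlock(
            side_cm_per_px=spec.scales.side_scale,
            top_cm_per_px=spec.scales.top_scale,
        ),
        metadata=spec.metadata,
    )


def load_annotation(path: str | Path, scales: ScaleParams | None = None) -> AnnotatedSpecimen:
    """Read one annotation JSON file into an :class:`AnnotatedSpecimen`."""
    try:
        doc = AnnotationDocument.model_validate_json(Path(path).read_text())
    except ValueError as e:
        raise AnnotationError(f"{path}: {e}") from e
    return document_to_specimen(doc, scales=scales)


def save_annotation(spec: AnnotatedSpecimen, path: str | Path) -> None:
    """Write a specimen to annotation JSON (round-trips exactly on text)."""
    doc = specimen_to_document(spec)
    Path(path).write_text(
        json.dumps(doc.model_dump(), indent=2, sort_keys=True) + "\n"
    )
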