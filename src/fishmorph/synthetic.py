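"""Synthetic 3D fish specimens with known landmarks and ground-truth traits.

The generator builds a piecewise-linear 3D body centerline — head segment,
three mid-body segments, tail segment — bent in the horizontal plane at the
segment joints (fish at rest curve sideways, not vertically; an out-of-plane
pitch profile is available behind a parameter for robustness studies).
Anatomical landmarks are placed on or symmetrically around the centerline:
height pairs vertically (head-up/down, small-up/down), width pairs laterally
(fin-left/right, middle-left/right), tail-fin tips behind the body/tail
junction with a vertical fork offset.

Ground-truth phenotypes are computed by applying the measurement pipeline's
own segment decomposition directly to the exact 3D coordinates (an
independent numpy code path on cm coordinates — no pixels, no calibration).
Defining truth by the decomposition rather than by centerline arc length
makes the noiseless round trip generate -> project -> measure an exact
oracle for the implementation; for straight fish the two definitions
coincide, which a test asserts separately.

World frame (cm): Y runs snout-to-tail (head at small Y, matching the
head-left image convention), X is lateral, Z is vertical downward.  The side
camera images (Y, Z), the top camera (Y, X); both are ideal orthographic
cameras with a pixel-per-cm scale and a principal offset.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import ScaleParams
from .geometry import Point2D, reconstruct_3d_length
from .morphometry import PhenotypeRecord
from .skeleton import (
    SIDE_LABELS,
    TOP_LABELS,
    AnnotatedSpecimen,
    SideKeypointSet,
    TopKeypointSet,
)

__all__ = [
    "FishParams",
    "FishSpecimen3D",
    "CameraModel",
    "GenerationError",
    "generate",
    "sample_params",
    "random_specimen",
    "default_cameras",
    "project",
    "perturb",
    "rasterize",
]

logger = logging.getLogger(__name__)


class GenerationError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class FishParams:
    """Shape parameters of one synthetic fish, lengths in cm, angles in degrees.

    Defaults emulate the channel catfish size class of the reference study
    (total length 12-17 cm) in a gently S-curved resting posture.
    """

    head_len: float = 3.0            # mouth -> head-middle chord
    mid_lens: tuple[float, float, float] = (2.5, 3.0, 3.0)  # head-middle -> tail junction
    tail_len: float = 2.8            # tail junction -> fin tip
    body_height: float = 2.3         # dorsoventral extent at head-up/down
    body_thickness: float = 2.1      # lateral extent at the pectoral fins
    tail_handle_height: float = 1.5  # dorsoventral extent of the caudal peduncle
    mid_width: float = 1.6           # lateral extent at the ventral fins
    tail_fork_up: float = 0.5        # vertical offset of the upper tail tip
    tail_fork_down: float = 0.5      # vertical offset of the lower tail tip
    # Longitudinal setback of each fork tip from the longest tail point.
    # Distinct values keep the two tail projections genuinely different
    # (a real fork is never perfectly symmetric), so the min-projection
    # rule picks one tip unambiguously.
    fork_back_up: float = 0.1
    fork_back_down: float = 0.3
    bend_angles_deg: tuple[float, float, float, float] = (8.0, -12.0, 10.0, -8.0)
    pitch_angles_deg: tuple[float, float, float, float, float] = (0.0,) * 5
    s2_fraction: float = 0.9         # gill point position along the head segment
    s12_back_offset: float = 0.3     # small-middle sits this far ahead of the junction
    s5_offset: float = 0.7           # anal-fin point this far ahead of small-middle
    s5_drop: float = 0.5             # ventral (downward) offset of the anal-fin point
    pose_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (X, Y, Z) cm

    def validate(self) -> None:
        positive = {
            "head_len": self.head_len,
            "tail_len": self.tail_len,
            "body_height": self.body_height,
            "body_thickness": self.body_thickness,
            "tail_handle_height": self.tail_handle_height,
            "mid_width": self.mid_width,
        }
        for name, v in positive.items():
            if not (math.isfinite(v) and v > 0):
                raise GenerationError(f"{name} must be positive, got {v!r}")
        if len(self.mid_lens) != 3 or any(l <= 0 for l in self.mid_lens):
            raise GenerationError(f"mid_lens must be three positive lengths, got {self.mid_lens!r}")
        if self.tail_fork_up < 0 or self.tail_fork_down < 0:
            raise GenerationError("tail fork offsets must be non-negative")
        if not (0 <= self.fork_back_up < self.tail_len and 0 <= self.fork_back_down < self.tail_len):
            raise GenerationError("fork setbacks must lie within the tail segment")
        if any(abs(a) >= 60.0 for a in self.bend_angles_deg):
            raise GenerationError("bend angles must stay within (-60, 60) degrees")
        if not 0.0 < self.s2_fraction <= 1.0:
            raise GenerationError("s2_fraction must be in (0, 1]")
        if not 0.0 < self.s12_back_offset < self.mid_lens[2]:
            raise GenerationError("s12_back_offset must fall inside the last mid segment")


@dataclass(frozen=True)
class FishSpecimen3D:
    """A generated specimen: 3D landmarks (cm) plus ground-truth phenotypes."""

    specimen_id: str
    params: FishParams
    landmarks3d: dict[str, np.ndarray]  # label -> (X, Y, Z) cm; includes midpoints
    truth: PhenotypeRecord


def _unit(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """Unit direction from yaw (about vertical, from +Y toward +X) and pitch."""
    yaw = math.radians(yaw_deg)
    pitch = math.radians(pitch_deg)
    return np.array(
        [math.cos(pitch) * math.sin(yaw), math.cos(pitch) * math.cos(yaw), math.sin(pitch)]
    )


def _lateral_normal(yaw_deg: float) -> np.ndarray:
    """Horizontal unit normal to a segment of the given yaw."""
    yaw = math.radians(yaw_deg)
    return np.array([math.cos(yaw), -math.sin(yaw), 0.0])


# --- independent ground-truth path: the decomposition applied in 3D (cm) ---

def _side2(p: np.ndarray) -> np.ndarray:
    """Side-camera plane coordinates (horizontal, vertical) of a 3D point."""
    return np.array([p[1], p[2]])


def _top2(p: np.ndarray) -> np.ndarray:
    """Top-camera plane coordinates (horizontal, lateral) of a 3D point."""
    return np.array([p[1], p[0]])


def _d(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(b - a))


def _cos_h(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute cosine of a plane segment against the shared horizontal axis."""
    v = b - a
    return abs(float(v[0])) / float(np.linalg.norm(v))


def _true_phenotypes(lm: dict[str, np.ndarray], specimen_id: str) -> PhenotypeRecord:
    side = {k: _side2(v) for k, v in lm.items() if k.startswith("S")}
    top = {k: _top2(v) for k, v in lm.items() if k.startswith("T")}

    bt = _d(top["T2"], top["T3"])
    bh = _d(side["S3"], side["S4"])
    thh = _d(side["S6"], side["S7"])
    hl = reconstruct_3d_length(
        _d(side["S1"], side["S2"]),
        _cos_h(side["S1"], side["S2"]),
        _cos_h(top["T1"], top["T10"]),
    )

    l_hm = reconstruct_3d_length(
        _d(side["S1"], side["S11"]),
        _cos_h(side["S1"], side["S11"]),
        _cos_h(top["T1"], top["T10"]),
    )
    tmp = _d(side["S11"], side["S12"]) + _d(side["S8"], side["S12"])
    poly = [top["T10"], top["T11"], top["T7"], top["T8"]]
    seg_lens = [_d(a, b) for a, b in zip(poly[:-1], poly[1:])]
    total = sum(seg_lens)
    cos_side_mid = _cos_h(side["S12"], side["S11"])
    bl = l_hm
    for seg_len, (a, b) in zip(seg_lens, zip(poly[:-1], poly[1:])):
        bl += reconstruct_3d_length(tmp * seg_len / total, cos_side_mid, _cos_h(b, a))

    axis = side["S11"] - side["S12"]
    axis_n = float(np.linalg.norm(axis))
    projections = {}
    for tip in ("S9", "S10"):
        v = side["S8"] - side[tip]
        projections[tip] = abs(float(v @ axis)) / axis_n
    chosen = "S9" if projections["S9"] <= projections["S10"] else "S10"
    tail = reconstruct_3d_length(
        projections[chosen],
        _cos_h(side[chosen], side["S8"]),
        _cos_h(top["T8"], top["T9"]),
    )
    fl = bl + tail

    span = (
        abs(float((side["S5"] - side["S12"]) @ axis))
        + abs(float((side["S12"] - side["S8"]) @ axis))
    ) / axis_n
    thw = reconstruct_3d_length(
        span, _cos_h(side["S12"], side["S11"]), _cos_h(top["T8"], top["T7"])
    )

    return PhenotypeRecord(
        specimen_id=specimen_id,
        full_length=fl,
        body_length=bl,
        body_height=bh,
        body_thickness=bt,
        head_length=hl,
        tail_handle_height=thh,
        tail_handle_width=thw,
    )


def generate(params: FishParams | None = None, specimen_id: str = "synthetic") -> FishSpecimen3D:
    """Build one specimen deterministically from its parameters.

    Randomness lives in :func:`sample_params` / :func:`random_specimen`;
    identical parameters always yield a bit-identical specimen.
    """
    p = params or FishParams()
    p.validate()

    seg_lens = (p.head_len, *p.mid_lens, p.tail_len)
    yaws = np.concatenate([[0.0], np.cumsum(p.bend_angles_deg)])
    dirs = [_unit(yaw, pitch) for yaw, pitch in zip(yaws, p.pitch_angles_deg)]

    nodes = [np.zeros(3)]
    for length, d in zip(seg_lens, dirs):
        nodes.append(nodes[-1] + length * d)
    n0, n1, n2, n3, n4, tip = nodes

    up = np.array([0.0, 0.0, -1.0])  # Z points down; "up" is negative Z
    lat1 = _lateral_normal(yaws[1])
    lat2 = _lateral_normal(yaws[2])

    lm: dict[str, np.ndarray] = {}
    lm["S1"] = lm["T1"] = n0
    lm["S2"] = n0 + p.s2_fraction * p.head_len * dirs[0]
    lm["S3"] = n1 + up * (p.body_height / 2)
    lm["S4"] = n1 - up * (p.body_height / 2)
    lm["S11"] = lm["T10"] = lm["T4"] = n1
    lm["T2"] = n1 + lat1 * (p.body_thickness / 2)
    lm["T3"] = n1 - lat1 * (p.body_thickness / 2)
    lm["T5"] = n2 + lat2 * (p.mid_width / 2)
    lm["T6"] = n2 - lat2 * (p.mid_width / 2)
    lm["T11"] = n2
    lm["T7"] = n3
    lm["S8"] = lm["T8"] = n4
    s12 = n4 - p.s12_back_offset * dirs[3]
    lm["S12"] = s12
    lm["S6"] = s12 + up * (p.tail_handle_height / 2)
    lm["S7"] = s12 - up * (p.tail_handle_height / 2)
    lm["S5"] = s12 - p.s5_offset * dirs[3] - up * p.s5_drop
    lm["T9"] = tip
    lm["S9"] = tip - p.fork_back_up * dirs[4] + up * p.tail_fork_up
    lm["S10"] = tip - p.fork_back_down * dirs[4] - up * p.tail_fork_down

    offset = np.asarray(p.pose_offset, dtype=float)
    lm = {k: v + offset for k, v in lm.items()}

    truth = _true_phenotypes(lm, specimen_id)
    if truth.full_length < truth.body_length:
        raise GenerationError("constructed specimen violates FL >= BL")
    return FishSpecimen3D(specimen_id=specimen_id, params=p, landmarks3d=lm, truth=truth)


def sample_params(seed: int | np.random.Generator) -> FishParams:
    """Draw realistic parameters for the 12-17 cm catfish size class."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Sample cumulative segment yaws (bounded so the body never doubles back
    # on the longitudinal axis), then convert to per-joint bend angles.
    yaws = rng.uniform(-30.0, 30.0, size=4)
    bends = np.diff(np.concatenate([[0.0], yaws]))
    # Guaranteed-distinct fork setbacks (see FishParams.fork_back_*).
    fork_a = rng.uniform(0.05, 0.3)
    fork_delta = rng.uniform(0.03, 0.15)
    fork_up_shorter = rng.random() < 0.5
    return FishParams(
        head_len=rng.uniform(2.4, 3.4),
        mid_lens=tuple(rng.uniform(2.2, 3.2, size=3)),
        tail_len=rng.uniform(2.2, 3.2),
        body_height=rng.uniform(1.7, 2.9),
        body_thickness=rng.uniform(1.5, 2.5),
        tail_handle_height=rng.uniform(1.1, 2.0),
        mid_width=rng.uniform(1.3, 2.0),
        tail_fork_up=rng.uniform(0.3, 0.7),
        tail_fork_down=rng.uniform(0.3, 0.7),
        fork_back_up=fork_a if fork_up_shorter else fork_a + fork_delta,
        fork_back_down=fork_a + fork_delta if fork_up_shorter else fork_a,
        bend_angles_deg=tuple(bends),
        s2_fraction=rng.uniform(0.85, 0.95),
        s12_back_offset=rng.uniform(0.2, 0.4),
        s5_offset=rng.uniform(0.5, 0.9),
        s5_drop=rng.uniform(0.3, 0.6),
        pose_offset=tuple(rng.uniform(-1.0, 1.0, size=3)),
    )


def random_specimen(seed: int, specimen_id: str | None = None) -> FishSpecimen3D:
    """A fully random specimen; a fixed seed reproduces it bit-identically."""
    return generate(sample_params(seed), specimen_id=specimen_id or f"synt-{seed:08d}")


@dataclass(frozen=True)
class CameraModel:
    """Ideal orthographic camera for one view.

    ``view`` selects the axis mapping: the side camera images (Y, Z), the top
    camera (Y, X); both share the longitudinal image-x axis.  ``px_per_cm``
    scales cm to pixels and ``offset`` shifts the principal point so the fish
    lands inside ``image_size`` (width, height).
    """

    view: str  # "side" | "top"
    px_per_cm: float = 30.0
    image_size: tuple[int, int] = (800, 480)
    offset: tuple[float, float] = (100.0, 240.0)

    def __post_init__(self) -> None:
        if self.view not in ("side", "top"):
            raise GenerationError(f"camera view must be 'side' or 'top', got {self.view!r}")
        if not self.px_per_cm > 0:
            raise GenerationError("px_per_cm must be positive")

    def project_point(self, p3d: np.ndarray) -> Point2D:
        plane = _side2(p3d) if self.view == "side" else _top2(p3d)
        return Point2D(
            float(plane[0] * self.px_per_cm + self.offset[0]),
            float(plane[1] * self.px_per_cm + self.offset[1]),
        )


def default_cameras(px_per_cm: float = 30.0) -> tuple[CameraModel, CameraModel]:
    side = CameraModel(view="side", px_per_cm=px_per_cm)
    top = CameraModel(view="top", px_per_cm=px_per_cm)
    return side, top


def desk_camera(view: str, size: int = 64) -> CameraModel:
    """A low-resolution square camera sized for detector experiments.

    Scales so the default fish size class (~18 cm with pose offset) spans
    most of a ``size`` x ``size`` frame with a clear margin on every border
    (keypoints flush against the frame edge are poorly localized by a
    padded convolutional network).
    """
    px_per_cm = size / 24.0
    return CameraModel(
        view=view,
        px_per_cm=px_per_cm,
        image_size=(size, size),
        offset=(3.0 * px_per_cm, size / 2.0),
    )


def project(
    spec3d: FishSpecimen3D,
    camera_side: CameraModel | None = None,
    camera_top: CameraModel | None = None,
) -> AnnotatedSpecimen:
    """Orthographically project a specimen into a dual-view annotation.

    Only the annotated landmarks are emitted (S1..S10, T1..T9); midpoints are
    re-derived downstream, exercising the same path real annotations take.
    Attached scales are the exact inverse of each camera's pixels-per-cm, so
    the noiseless round trip through ``measure`` reproduces ``spec3d.truth``.
    """
    if camera_side is None or camera_top is None:
        d_side, d_top = default_cameras()
        camera_side = camera_side or d_side
        camera_top = camera_top or d_top

    def project_view(camera: CameraModel, labels, symbols) -> dict[str, tuple[float, float]]:
        out = {}
        w, h = camera.image_size
        for label, sym in zip(labels, symbols):
            pt = camera.project_point(spec3d.landmarks3d[sym])
            if not (0 <= pt.x <= w and 0 <= pt.y <= h):
                logger.warning(
                    "specimen %s: %s landmark %s projects outside the %dx%d image",
                    spec3d.specimen_id, camera.view, sym, w, h,
                )
            out[label] = (pt.x, pt.y)
        return out

    side_pts = project_view(camera_side, SIDE_LABELS, [f"S{i}" for i in range(1, 11)])
    top_pts = project_view(camera_top, TOP_LABELS, [f"T{i}" for i in range(1, 10)])
    return AnnotatedSpecimen(
        specimen_id=spec3d.specimen_id,
        side=SideKeypointSet.from_labels(side_pts),
        top=TopKeypointSet.from_labels(top_pts),
        scales=ScaleParams(
            side_scale=1.0 / camera_side.px_per_cm,
            top_scale=1.0 / camera_top.px_per_cm,
        ),
        side_image_size=camera_side.image_size,
        top_image_size=camera_top.image_size,
        metadata={"source": "synthetic"},
    )


def perturb(spec: AnnotatedSpecimen, sigma: float, seed: int) -> AnnotatedSpecimen:
    """Add i.i.d. Gaussian noise (std ``sigma`` px) to every annotated keypoint.

    Models annotation/detection jitter; ``sigma=0`` returns an identical
    specimen.  A fixed seed reproduces the perturbation exactly.
    """
    if sigma < 0:
        raise GenerationError("sigma must be >= 0")
    if sigma == 0:
        return spec
    rng = np.random.default_rng(seed)
    side_pts = {
        l: (p.x + rng.normal(0.0, sigma), p.y + rng.normal(0.0, sigma))
        for l, p in spec.side.to_labels().items()
    }
    top_pts = {
        l: (p.x + rng.normal(0.0, sigma), p.y + rng.normal(0.0, sigma))
        for l, p in spec.top.to_labels().items()
    }
    return dataclasses.replace(
        spec,
        side=SideKeypointSet.from_labels(side_pts),
        top=TopKeypointSet.from_labels(top_pts),
    )


def rasterize(
    spec3d: FishSpecimen3D | None,
    camera: CameraModel,
    seed: int = 0,
    foreground: float = 0.8,
    background_noise: float = 0.08,
) -> np.ndarray:
    """Render a filled grayscale silhouette of one view, values in [0, 1].

    The body outline is a polygon through the view's landmarks (with small
    synthetic half-width points where the outline crosses centerline
    landmarks), filled and slightly dilated so every landmark pixel lies
    inside the mask, over a uniform-noise background.  Deterministic given
    the seed.  ``spec3d=None`` yields a background-only image.
    """
    from skimage.draw import polygon as draw_polygon
    from skimage.morphology import dilation

    rng = np.random.default_rng(seed)
    w, h = camera.image_size
    img = rng.uniform(0.0, background_noise, size=(h, w)).astype(np.float32)
    if spec3d is None:
        return img

    lm = spec3d.landmarks3d
    p = spec3d.params
    if camera.view == "side":
        outline3d = [lm["S1"], lm["S3"], lm["S6"], lm["S9"], lm["S10"], lm["S7"], lm["S4"]]
    else:
        up_lat = np.array([1.0, 0.0, 0.0])
        half7 = 0.35 * p.mid_width
        half8 = 0.2 * p.mid_width
        outline3d = [
            lm["T1"], lm["T2"], lm["T5"],
            lm["T7"] + up_lat * half7, lm["T8"] + up_lat * half8, lm["T9"],
            lm["T8"] - up_lat * half8, lm["T7"] - up_lat * half7,
            lm["T6"], lm["T3"],
        ]
    pts = [camera.project_point(q) for q in outline3d]
    rows = np.array([q.y for q in pts])
    cols = np.array([q.x for q in pts])
    rr, cc = draw_polygon(rows, cols, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    mask = dilation(mask, footprint=np.ones((5, 5), dtype=bool))
    img[mask] = foreground
    return img
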