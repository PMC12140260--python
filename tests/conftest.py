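import numpy as np
import pytest

from fishmorph.calibration import ScaleParams
from fishmorph.skeleton import AnnotatedSpecimen, SideKeypointSet, TopKeypointSet


def straight_specimen(side_scale: float = 0.1, top_scale: float = 0.1) -> AnnotatedSpecimen:
    """An axis-aligned fish whose measurements are hand-computable.

    Side: S1=(0,50), S11=(30,50) via S3/S4 at x=30, S12=(80,50) via S6/S7 at
    x=80, S8=(100,50); tail tips S9=(115,45), S10=(118,55); S5=(70,60).
    Top: all polyline points on y=100 with T10=(30,100), T11=(55,100),
    T7=(75,100), T8=(100,100), T9=(125,100).  With all cosines 1 the 3D
    reconstruction is the identity and every trait is a planar length times
    the scale.
    """
    side = SideKeypointSet.from_labels(
        {
            "side-head": (0, 50),
            "head-fin": (30, 50),
            "head-up": (30, 38),
            "head-down": (30, 62),
            "front-small": (70, 60),
            "small-up": (80, 42.5),
            "small-down": (80, 57.5),
            "side-tail": (100, 50),
            "tail-up": (115, 45),
            "tail-down": (118, 55),
        }
    )
    top = TopKeypointSet.from_labels(
        {
            "top-head": (0, 100),
            "fin-right": (30, 90),
            "fin-left": (30, 110),
            "fin-up": (30, 100),
            "middle-right": (55, 92),
            "middle-left": (55, 108),
            "middle": (75, 100),
            "small-tail": (100, 100),
            "top-tail": (125, 100),
        }
    )
    return AnnotatedSpecimen(
        specimen_id="straight",
        side=side,
        top=top,
        scales=ScaleParams(side_scale, top_scale),
        side_image_size=(200, 120),
        top_image_size=(200, 160),
    )


@pytest.fixture
def straight_fish() -> AnnotatedSpecimen:
    return straight_specimen()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
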