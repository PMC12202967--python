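"""Shared geometric fixtures: hand-built faces with known measurements."""

import math

import numpy as np
import pytest

from smileframe import FacialLandmarkSet, Landmark2D


def make_set(subject_id, view, points, incisal=None, lip=None):
    lset = FacialLandmarkSet(subject_id=subject_id, view=view)
    for name, (x, y) in points.items():
        lset.add(Landmark2D(name, float(x), float(y)))
    lset.incisal_edge_points = [tuple(map(float, p)) for p in (incisal or [])]
    lset.lower_lip_points = [tuple(map(float, p)) for p in (lip or [])]
    return lset


def symmetric_smile_points():
    """Perfectly bilaterally symmetric smile view: canthi at (+-300, 0),
    every midline landmark on x = 0, commissures equidistant."""
    return {
        "LC_R": (-300.0, 0.0),
        "LC_L": (300.0, 0.0),
        "N": (0.0, -10.0),
        "PRN": (0.0, 150.0),
        "PHT": (0.0, 255.0),
        "DM": (0.0, 290.0),
        "CH_R": (-120.0, 285.0),
        "CH_L": (120.0, 285.0),
        "ULC": (0.0, 285.0),
        "LLI": (0.0, 400.0),
    }


def symmetric_curves():
    us = np.linspace(-90.0, 90.0, 7)
    incisal = [(u, -0.002 * u**2 + 300.0) for u in us]
    lip = [(u, -0.003 * u**2 + 320.0) for u in us]
    return incisal, lip


@pytest.fixture
def symmetric_smile_set():
    incisal, lip = symmetric_curves()
    return make_set("sym", "frontal_smile", symmetric_smile_points(),
                    incisal, lip)


def rest_points():
    """Rest view with forced vertical levels: TR v=0, LC pair v=100,
    LN pair v=200, CH pair v=280, ME v=400 (so TR-ME=400, LC-CH=180,
    LN-CH=80) and CH at (-95,280)/(95,280) (so CH r-l = 190)."""
    return {
        "TR": (0.0, 0.0),
        "TS_R": (-220.0, 60.0),
        "TS_L": (220.0, 60.0),
        "LC_R": (-150.0, 100.0),
        "LC_L": (150.0, 100.0),
        "LN_R": (-60.0, 200.0),
        "LN_L": (60.0, 200.0),
        "CH_R": (-95.0, 280.0),
        "CH_L": (95.0, 280.0),
        "ME": (0.0, 400.0),
    }


@pytest.fixture
def rest_set():
    return make_set("sym", "frontal_rest", rest_points())


def transform_set(lset, angle_deg=0.0, scale=1.0, translation=(0.0, 0.0)):
    """Apply a similarity transform to every coordinate of a landmark set."""
    th = math.radians(angle_deg)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    t = np.asarray(translation, dtype=float)

    def tx(p):
        return tuple(scale * rot @ np.asarray(p, dtype=float) + t)

    points = {name: tx(lm.xy) for name, lm in lset.points.items()}
    return make_set(
        lset.subject_id, lset.view, points,
        [tx(p) for p in lset.incisal_edge_points],
        [tx(p) for p in lset.lower_lip_points],
    )


def mirror_set(lset, axis_x=0.0):
    """Mirror a face about the vertical image line x = axis_x.

    Side-carrying names swap (the mirrored subject's right is the original
    subject's left)."""
    def swap(name):
        if name.endswith("_R"):
            return name[:-2] + "_L"
        if name.endswith("_L"):
            return name[:-2] + "_R"
        return name

    def mx(p):
        return (2.0 * axis_x - p[0], p[1])

    points = {swap(name): mx(lm.xy) for name, lm in lset.points.items()}
    return make_set(
        lset.subject_id, lset.view, points,
        [mx(p) for p in lset.incisal_edge_points],
        [mx(p) for p in lset.lower_lip_points],
    )
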