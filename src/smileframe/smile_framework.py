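"""Smile-framework classifiers and tooth-crown metrics.

Five categorical attributes of the posed smile plus two metrics of the
maxillary right central incisor:

* smile arc — consonant when the maxillary incisal-edge curve and the lower
  lip curve both dip centrally (parallel downward-convex arcs);
* upper-lip curvature — up / straight / down from the mouth corners' height
  relative to the upper-lip center;
* smile line — high / medium / low from clinical-crown exposure and gingival
  display;
* smile width — most posterior tooth type shown (first premolar ... second
  molar);
* tooth shape — triangular / oval / square from the crown DP%;
* tooth size — width-to-length ratio against the divine proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, UnsupportedCategoryError
from .beauty_frame import BeautyFrame, project_u, project_v
from .facial_proportions import golden_percent
from .landmark_model import MIN_CURVE_POINTS, ToothMeasurement

SMILE_ARC_LEVELS = ("consonant", "non_consonant")
LIP_CURVATURE_LEVELS = ("up", "straight", "down")
SMILE_LINE_LEVELS = ("high", "medium", "low")
SMILE_WIDTH_LEVELS = (
    "first_premolar", "second_premolar", "first_molar", "second_molar"
)
TOOTH_SHAPE_LEVELS = ("triangular", "oval", "square")

#: FDI tooth-type digit of the last visible tooth -> smile-width category.
SMILE_WIDTH_BY_TOOTH_CODE = {
    4: "first_premolar",
    5: "second_premolar",
    6: "first_molar",
    7: "second_molar",
}

#: DP% class boundaries: triangular below 43, square above 57, oval between
#: (boundary values fall in the oval class).
DP_TRIANGULAR_MAX = 43.0
DP_SQUARE_MIN = 57.0

#: Default curvature threshold (px^-1) below which a fitted arc counts as
#: flat; sub-threshold curvature must not flip the consonance call.
DEFAULT_FLATNESS_TOL = 1e-4

#: Default lip-curvature dead band as a fraction of the frame height.
DEFAULT_LIP_TOL_FRAC = 0.02


@dataclass(frozen=True)
class SmileLineObservation:
    """Clinical-crown exposure of the maxillary central during the smile.

    ``exposure_fraction`` is the visible fraction of the clinical crown
    (values above 1 mean the full crown plus gingiva is shown);
    ``gingival_display`` records what soft tissue is visible above it.
    """

    exposure_fraction: float
    gingival_display: str  # continuous_band | papilla_only | none

    def __post_init__(self):
        if self.exposure_fraction < 0:
            raise ValueError("exposure_fraction must be >= 0")
        if self.gingival_display not in (
            "continuous_band", "papilla_only", "none"
        ):
            raise ValueError(
                f"unknown gingival_display {self.gingival_display!r}"
            )


@dataclass(frozen=True)
class SmileAssessment:
    """All smile-framework attributes for one subject."""

    arc: str
    lip_curvature: str
    smile_line: str
    smile_width: str
    tooth_shape: str
    dp_percent: float
    wl_ratio: float
    wl_golden_percent: float


# --------------------------------------------------------------------------
# Geometric classifiers
# --------------------------------------------------------------------------


def _fit_quadratic(points, frame: BeautyFrame) -> float:
    """Least-squares curvature coefficient a of v = a u^2 + b u + c."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < MIN_CURVE_POINTS:
        raise DegenerateFitError(
            f"quadratic fit needs >= {MIN_CURVE_POINTS} points, "
            f"got {pts.shape[0]}"
        )
    u = np.array([project_u(frame, p) for p in pts])
    v = np.array([project_v(frame, p) for p in pts])
    if len(np.unique(u)) < 3:
        raise DegenerateFitError(
            "quadratic fit is singular: fewer than 3 distinct u positions"
        )
    # center and scale u for conditioning; only the quadratic coefficient
    # matters and it rescales deterministically
    u0 = u.mean()
    s = u.std()
    if s == 0.0:
        raise DegenerateFitError("quadratic fit is singular: zero u spread")
    coeffs = np.polyfit((u - u0) / s, v, 2)
    return float(coeffs[0] / s**2)


def classify_smile_arc(
    incisal_points,
    lower_lip_points,
    frame: BeautyFrame,
    flatness_tol: float = DEFAULT_FLATNESS_TOL,
) -> str:
    """Consonant if incisal edge and lower lip are parallel downward arcs.

    Both polylines are projected into frame coordinates and fitted with a
    quadratic; the smile is consonant when both curvature coefficients lie
    below ``-flatness_tol`` (centrally dipping with v downward), i.e. the
    incisal curve follows the lower lip. Direction, not magnitude, decides.
    """
    a_inc = _fit_quadratic(incisal_points, frame)
    a_lip = _fit_quadratic(lower_lip_points, frame)
    if a_inc < -flatness_tol and a_lip < -flatness_tol:
        return "consonant"
    return "non_consonant"


def classify_lip_curvature(
    ch_r,
    ch_l,
    ulc,
    frame: BeautyFrame,
    tol_frac: float = DEFAULT_LIP_TOL_FRAC,
) -> str:
    """Upper-lip curvature from mouth-corner height vs the upper-lip center.

    Delta = v(ULC) - mean v(commissures) is positive when the corners sit
    above the lip center (y grows downward): up if Delta exceeds
    ``tol_frac * frame.height``, down if below its negative, else straight.
    """
    if not (0 <= tol_frac < 1):
        raise ValueError("tol_frac must be in [0, 1)")
    v_corners = 0.5 * (project_v(frame, ch_r) + project_v(frame, ch_l))
    delta = project_v(frame, ulc) - v_corners
    band = tol_frac * frame.height
    if delta > band:
        return "up"
    if delta < -band:
        return "down"
    return "straight"


def classify_smile_line(obs: SmileLineObservation) -> str:
    """High / medium / low smile line.

    High: the entire clinical crown plus a continuous gingival band shows.
    Medium: 75-100% of the crown with at most the interdental papilla.
    Low: less than 75% of the crown.
    """
    if obs.exposure_fraction >= 1.0 and obs.gingival_display == "continuous_band":
        return "high"
    if obs.exposure_fraction >= 0.75:
        return "medium"
    return "low"


def classify_smile_width(last_visible_tooth: int) -> str:
    """Smile-width category from the FDI tooth-type digit (4..7)."""
    try:
        return SMILE_WIDTH_BY_TOOTH_CODE[int(last_visible_tooth)]
    except (KeyError, ValueError, TypeError):
        raise UnsupportedCategoryError(
            f"unsupported last-visible-tooth code {last_visible_tooth!r} "
            "(expected FDI tooth-type digit 4..7)"
        ) from None


# --------------------------------------------------------------------------
# Tooth metrics
# --------------------------------------------------------------------------


def tooth_shape(
    m: ToothMeasurement, dp_definition: str = "as_printed"
) -> tuple[float, str]:
    """DP% of the crown and its shape class.

    ``as_printed`` uses DP% = length / width * 100 with triangular < 43,
    square > 57 and oval between (boundaries inclusive in oval). The
    ``width_over_length`` switch inverts the quotient for users who read the
    index the other way round; class thresholds are unchanged.
    """
    if dp_definition == "as_printed":
        dp = m.length / m.width * 100.0
    elif dp_definition == "width_over_length":
        dp = m.width / m.length * 100.0
    else:
        raise ValueError(f"unknown dp_definition {dp_definition!r}")
    if dp < DP_TRIANGULAR_MAX:
        shape = "triangular"
    elif dp > DP_SQUARE_MIN:
        shape = "square"
    else:
        shape = "oval"
    return dp, shape


def tooth_size(m: ToothMeasurement) -> tuple[float, float]:
    """Width-to-length ratio and its percent of the divine proportion."""
    wl = m.width / m.length
    return wl, golden_percent(wl)


def assess_smile(
    lset,
    frame: BeautyFrame,
    obs: SmileLineObservation,
    last_visible_tooth: int,
    m: ToothMeasurement,
    flatness_tol: float = DEFAULT_FLATNESS_TOL,
    lip_tol_frac: float = DEFAULT_LIP_TOL_FRAC,
    dp_definition: str = "as_printed",
) -> SmileAssessment:
    """Run every smile classifier for one subject."""
    arc = classify_smile_arc(
        lset.incisal_edge_points, lset.lower_lip_points, frame, flatness_tol
    )
    lip = classify_lip_curvature(
        lset.xy("CH_R"), lset.xy("CH_L"), lset.xy("ULC"), frame, lip_tol_frac
    )
    line = classify_smile_line(obs)
    width_cat = classify_smile_width(last_visible_tooth)
    dp, shape = tooth_shape(m, dp_definition)
    wl, wl_pct = tooth_size(m)
    return SmileAssessment(
        arc=arc, lip_curvature=lip, smile_line=line, smile_width=width_cat,
        tooth_shape=shape, dp_percent=dp, wl_ratio=wl, wl_golden_percent=wl_pct,
    )
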