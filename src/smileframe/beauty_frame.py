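"""Beauty frame construction and relative midline values (RFV / RCV).

The beauty frame is the rectangle bounded above by the inter-canthal line,
laterally by the perpendiculars through each external canthus, and below by
the parallel line through the lowest point of the lower lip. Its vertical
bisector is the operational facial midline: landmark positions are expressed
as the distance ``u`` from the subject-right lateral border, normalized by
the half-width ``F``.

* RFV_i = u(landmark_i) / F   (facial-midline relative value; 1 = on midline)
* RCV_i = u(landmark_i) / Cx  (commissure-midline relative value, where
  Cx = u of the inter-commissure midpoint)

Values below 1 mean deviation toward the subject's right, above 1 toward the
subject's left. The identity RCV_i * RFV5 = RFV_i holds exactly because all
quantities share the same origin and denominator chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, LandmarkValidationError
from .landmark_model import FacialLandmarkSet, validate_for

#: Canonical landmark order used for hierarchy tie-breaks; keys are the RFV
#: slots, values the display names used in reports.
RFV_LANDMARK_NAMES = {
    "rfv1": "nasion",
    "rfv2": "nose tip",
    "rfv3": "philtrum",
    "rfv5": "commissure midline",
    "rfv4": "dental midline",
}
CANONICAL_ORDER = ("nasion", "nose tip", "philtrum", "commissure midline",
                   "dental midline")


@dataclass(frozen=True)
class BeautyFrame:
    """Canthal-aligned facial coordinate system.

    ``origin`` is the subject-right external canthus; ``u_axis`` points from
    it toward the left canthus; ``v_axis`` is the perpendicular pointing
    toward the lower boundary (through LLI). ``width`` is the inter-canthal
    distance (so ``F = width / 2``), ``height`` the perpendicular distance
    from the canthal line to the lower boundary.
    """

    origin: tuple[float, float]
    u_axis: tuple[float, float]
    v_axis: tuple[float, float]
    width: float
    height: float

    @property
    def F(self) -> float:
        """Half-width of the frame: distance border-to-facial-midline."""
        return self.width / 2.0


@dataclass(frozen=True)
class RFVSet:
    """Relative facial-midline values for the five midline landmarks."""

    rfv1: float  # nasion
    rfv2: float  # nose tip (pronasale)
    rfv3: float  # philtrum tip
    rfv4: float  # dental midline
    rfv5: float  # commissure midline

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("rfv1", "rfv2", "rfv3", "rfv4", "rfv5")}


@dataclass(frozen=True)
class RCVSet:
    """Relative commissure-midline values for four midline landmarks."""

    rcv1: float  # nasion
    rcv2: float  # nose tip
    rcv3: float  # philtrum tip
    rcv4: float  # dental midline

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("rcv1", "rcv2", "rcv3", "rcv4")}


# --------------------------------------------------------------------------
# Frame construction and projection
# --------------------------------------------------------------------------


def canthal_axes(lc_r, lc_l):
    """Orthonormal (origin, u, v) from the two canthi.

    ``u`` runs from the subject-right canthus toward the left one; ``v`` is
    its perpendicular oriented toward the lower face. Because y grows
    downward in image coordinates and head roll is small, "toward the lower
    face" is the choice with positive y component (ties broken by positive
    x, for the degenerate quarter-turn case).
    """
    lc_r = np.asarray(lc_r, dtype=float)
    lc_l = np.asarray(lc_l, dtype=float)
    axis = lc_l - lc_r
    width = float(np.hypot(*axis))
    if width == 0.0:
        raise DegenerateGeometryError(
            "degenerate frame: the two external canthi coincide"
        )
    u = axis / width
    v = np.array([-u[1], u[0]])
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    return lc_r, u, v, width


def build_frame(lset: FacialLandmarkSet) -> BeautyFrame:
    """Construct the beauty frame from a smile-view landmark set."""
    report = validate_for(lset, "frame")
    if not report.ok:
        raise LandmarkValidationError(
            f"subject {lset.subject_id!r}: " + "; ".join(report.reasons)
        )
    origin, u, v, width = canthal_axes(lset.xy("LC_R"), lset.xy("LC_L"))
    lli = np.asarray(lset.xy("LLI"), dtype=float)
    height = float(v @ (lli - origin))
    if height <= 0.0:
        raise DegenerateGeometryError(
            "degenerate frame: lowest lower-lip point on or above the "
            "canthal line"
        )
    return BeautyFrame(
        origin=tuple(origin), u_axis=tuple(u), v_axis=tuple(v),
        width=width, height=height,
    )


def project_u(frame: BeautyFrame, point) -> float:
    """Distance of ``point`` from the subject-right lateral border (pixels).

    u(LC_R) = 0 and u(LC_L) = 2F by construction; the value does not depend
    on where the point sits vertically.
    """
    p = np.asarray(point, dtype=float) - np.asarray(frame.origin)
    return float(p @ np.asarray(frame.u_axis))


def project_v(frame: BeautyFrame, point) -> float:
    """Perpendicular distance of ``point`` below the canthal line (pixels)."""
    p = np.asarray(point, dtype=float) - np.asarray(frame.origin)
    return float(p @ np.asarray(frame.v_axis))


# --------------------------------------------------------------------------
# RFV / RCV
# --------------------------------------------------------------------------

_RFV_LANDMARKS = ("N", "PRN", "PHT", "DM", "CH_R", "CH_L")


def commissure_midpoint_u(frame: BeautyFrame, lset: FacialLandmarkSet) -> float:
    """u-coordinate Cx of the inter-commissure midpoint."""
    return 0.5 * (
        project_u(frame, lset.xy("CH_R")) + project_u(frame, lset.xy("CH_L"))
    )


def compute_rfv(frame: BeautyFrame, lset: FacialLandmarkSet) -> RFVSet:
    """Relative facial-midline values: u(landmark) / F for each landmark.

    rfv5 is the commissure midline itself (Cx / F)."""
    missing = [n for n in _RFV_LANDMARKS if not lset.has(n)]
    if missing:
        raise LandmarkValidationError(
            "missing landmarks for RFV: " + ", ".join(missing)
        )
    F = frame.F
    return RFVSet(
        rfv1=project_u(frame, lset.xy("N")) / F,
        rfv2=project_u(frame, lset.xy("PRN")) / F,
        rfv3=project_u(frame, lset.xy("PHT")) / F,
        rfv4=project_u(frame, lset.xy("DM")) / F,
        rfv5=commissure_midpoint_u(frame, lset) / F,
    )


def compute_rcv(frame: BeautyFrame, lset: FacialLandmarkSet) -> RCVSet:
    """Relative commissure-midline values: u(landmark) / Cx.

    The denominator is the u-coordinate of the inter-commissure midpoint
    measured from the subject-right lateral border — the reading under which
    perfect symmetry yields RCV = 1 and RCV_i * RFV5 = RFV_i identically.
    """
    missing = [n for n in _RFV_LANDMARKS if not lset.has(n)]
    if missing:
        raise LandmarkValidationError(
            "missing landmarks for RCV: " + ", ".join(missing)
        )
    cx = commissure_midpoint_u(frame, lset)
    if cx == 0.0:
        raise DegenerateGeometryError(
            "commissure midpoint lies on the subject-right lateral border "
            "(zero RCV denominator)"
        )
    return RCVSet(
        rcv1=project_u(frame, lset.xy("N")) / cx,
        rcv2=project_u(frame, lset.xy("PRN")) / cx,
        rcv3=project_u(frame, lset.xy("PHT")) / cx,
        rcv4=project_u(frame, lset.xy("DM")) / cx,
    )


def classify_side(value: float, tol: float = 0.0) -> str:
    """Deviation side implied by an RFV/RCV value.

    Below ``1 - tol`` the landmark deviates toward the subject's right,
    above ``1 + tol`` toward the left, otherwise it is centered. The default
    tolerance 0 is the strict reading (any deviation counts).
    """
    if not value > 0:
        raise ValueError("RFV/RCV values must be positive")
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    if value < 1.0 - tol:
        return "right"
    if value > 1.0 + tol:
        return "left"
    return "centered"


def landmark_hierarchy(rfv_sets) -> list[str]:
    """Order the five landmarks by mean RFV, descending (left to right).

    Ties are broken by the canonical order (nasion, nose tip, philtrum,
    commissure midline, dental midline).
    """
    rfv_sets = list(rfv_sets)
    if not rfv_sets:
        raise ValueError("empty RFV collection")
    means = {
        slot: float(np.mean([getattr(s, slot) for s in rfv_sets]))
        for slot in ("rfv1", "rfv2", "rfv3", "rfv4", "rfv5")
    }
    names = [(RFV_LANDMARK_NAMES[slot], means[slot]) for slot in means]
    names.sort(key=lambda nm: (-nm[1], CANONICAL_ORDER.index(nm[0])))
    return [n for n, _ in names]
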