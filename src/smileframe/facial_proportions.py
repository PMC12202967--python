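"""Vertical/transverse facial distances, their ratios and golden percents.

Nine vertical spans (TR-ME, LC-ME, TR-LC, TR-LN, LN-ME, LC-LN, LC-CH, CH-ME,
LN-CH) are measured as perpendicular separations along the canthal-frame
v-axis, so a rolled head changes nothing; bilateral landmarks contribute the
mean v of their pair. Three transverse spans (CH, LC, TS right-to-left) are
straight point-to-point distances. Ten ratios are formed from these and each
is also expressed as a percent of the divine proportion, with 1.618 == 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, LandmarkValidationError
from .beauty_frame import canthal_axes
from .landmark_model import FacialLandmarkSet, validate_for

#: The reference divine (golden) proportion, fixed at the conventional
#: three-decimal value rather than (1+sqrt(5))/2.
GOLDEN_RATIO = 1.618

VERTICAL_DISTANCES = (
    "TR_ME", "LC_ME", "TR_LC", "TR_LN", "LN_ME", "LC_LN", "LC_CH",
    "CH_ME", "LN_CH",
)
TRANSVERSE_DISTANCES = ("CH_rl", "LC_rl", "TS_rl")

#: Ratio name -> (numerator distance, denominator distance), in print order.
RATIO_DEFINITIONS = {
    "TR-ME:LC-ME": ("TR_ME", "LC_ME"),
    "LC-ME:TR-LC": ("LC_ME", "TR_LC"),
    "TR-LN:LN-ME": ("TR_LN", "LN_ME"),
    "LN-ME:LC-LN": ("LN_ME", "LC_LN"),
    "LC-CH:CH-ME": ("LC_CH", "CH_ME"),
    "LC-LN:LN-CH": ("LC_LN", "LN_CH"),
    "CH-ME:LN-CH": ("CH_ME", "LN_CH"),
    "CH(r-l):LN(r-l)": ("CH_rl", "LN_rl"),
    "LC(r-l):CH(r-l)": ("LC_rl", "CH_rl"),
    "TS(r-l):LC(r-l)": ("TS_rl", "LC_rl"),
}

VERTICAL_RATIOS = tuple(list(RATIO_DEFINITIONS)[:7])
TRANSVERSE_RATIOS = tuple(list(RATIO_DEFINITIONS)[7:])


@dataclass(frozen=True)
class ProportionDistances:
    """The twelve linear measurements (pixels) behind the ten ratios.

    ``LN_rl`` is measured alongside the three printed transverse spans
    because the CH(r-l):LN(r-l) ratio needs it.
    """

    TR_ME: float
    LC_ME: float
    TR_LC: float
    TR_LN: float
    LN_ME: float
    LC_LN: float
    LC_CH: float
    CH_ME: float
    LN_CH: float
    CH_rl: float
    LC_rl: float
    TS_rl: float
    LN_rl: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class FacialRatios:
    """The ten dimensionless proportions with their golden percents."""

    ratios: dict[str, float]
    golden_percents: dict[str, float]


def measure_distances(lset: FacialLandmarkSet) -> ProportionDistances:
    """Measure the vertical and transverse spans on a rest-view set."""
    report = validate_for(lset, "proportions")
    if not report.ok:
        raise LandmarkValidationError(
            f"subject {lset.subject_id!r}: " + "; ".join(report.reasons)
        )
    origin, _u, v_axis, _w = canthal_axes(lset.xy("LC_R"), lset.xy("LC_L"))

    def v_of(name: str) -> float:
        p = np.asarray(lset.xy(name), dtype=float) - origin
        return float(p @ v_axis)

    # bilateral landmarks enter vertical spans at their pair-mean v
    v = {
        "TR": v_of("TR"),
        "ME": v_of("ME"),
        "LC": 0.5 * (v_of("LC_R") + v_of("LC_L")),
        "LN": 0.5 * (v_of("LN_R") + v_of("LN_L")),
        "CH": 0.5 * (v_of("CH_R") + v_of("CH_L")),
    }

    def span(a: str, b: str) -> float:
        return abs(v[a] - v[b])

    def across(stem: str) -> float:
        r = np.asarray(lset.xy(f"{stem}_R"), dtype=float)
        l = np.asarray(lset.xy(f"{stem}_L"), dtype=float)
        return float(np.hypot(*(l - r)))

    return ProportionDistances(
        TR_ME=span("TR", "ME"), LC_ME=span("LC", "ME"), TR_LC=span("TR", "LC"),
        TR_LN=span("TR", "LN"), LN_ME=span("LN", "ME"), LC_LN=span("LC", "LN"),
        LC_CH=span("LC", "CH"), CH_ME=span("CH", "ME"), LN_CH=span("LN", "CH"),
        CH_rl=across("CH"), LC_rl=across("LC"), TS_rl=across("TS"),
        LN_rl=across("LN"),
    )


def compute_ratios(d: ProportionDistances) -> FacialRatios:
    """Form the ten named ratios (numerator:denominator in print order)."""
    dd = d.as_dict()
    ratios: dict[str, float] = {}
    for name, (num, den) in RATIO_DEFINITIONS.items():
        if dd[den] == 0.0:
            raise DegenerateGeometryError(
                f"zero denominator distance {den} for ratio {name}"
            )
        if dd[num] < 0 or dd[den] < 0:
            raise DegenerateGeometryError(f"negative distance in ratio {name}")
        ratios[name] = dd[num] / dd[den]
    percents = {name: golden_percent(r) for name, r in ratios.items()}
    return FacialRatios(ratios=ratios, golden_percents=percents)


def golden_percent(ratio: float) -> float:
    """Express a ratio as a percent of the divine proportion (1.618 = 100)."""
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return ratio / GOLDEN_RATIO * 100.0


def golden_deviation(ratio: float) -> float:
    """Signed percent deviation from the divine proportion (1.618 -> 0)."""
    return golden_percent(ratio) - 100.0
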