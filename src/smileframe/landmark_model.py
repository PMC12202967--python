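"""Landmark vocabulary, coordinate conventions, validation, and file schemas.

Conventions used throughout the package:

* Coordinates are image pixels with *y increasing downward* (raster order).
* Anatomical side is carried by the landmark NAME (``_R``/``_L`` suffix means
  the SUBJECT's right/left), never inferred from x ordering, so mirrored or
  rotated images need no special handling.
* All ratios and classifications downstream are scale-free; the optional
  ``calibration_mm_per_px`` factor only converts reported absolute distances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    DuplicateLandmarkError,
    LandmarkValidationError,
    SchemaError,
)

# --------------------------------------------------------------------------
# Controlled vocabulary
# --------------------------------------------------------------------------

#: Midline (unsided) landmarks.
MIDLINE_LANDMARKS = frozenset(
    {"TR", "ME", "N", "PRN", "PHT", "DM", "LLI", "ULC"}
)

#: Bilateral landmark stems; each appears as ``<stem>_R`` and ``<stem>_L``.
BILATERAL_STEMS = ("TS", "LC", "LN", "CH")

SIDED_LANDMARKS = frozenset(
    f"{stem}_{side}" for stem in BILATERAL_STEMS for side in ("R", "L")
)

#: The full controlled vocabulary of point landmark names.
VOCABULARY = MIDLINE_LANDMARKS | SIDED_LANDMARKS

VIEWS = ("frontal_rest", "frontal_smile", "intraoral")

#: Landmarks required per analysis kind (curve-point requirements are
#: handled separately for the smile analysis).
REQUIRED_LANDMARKS = {
    "proportions": (
        "TR", "ME",
        "TS_R", "TS_L", "LC_R", "LC_L", "LN_R", "LN_L", "CH_R", "CH_L",
    ),
    "frame": ("LC_R", "LC_L", "N", "PRN", "PHT", "DM", "LLI", "CH_R", "CH_L"),
    "smile": ("CH_R", "CH_L", "ULC"),
}

#: Minimum number of support points per smile curve (quadratic fit).
MIN_CURVE_POINTS = 3


def side_of(name: str) -> str:
    """Anatomical side implied by a landmark name."""
    if name.endswith("_R"):
        return "right"
    if name.endswith("_L"):
        return "left"
    return "midline"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Landmark2D:
    """A single named, sided point in image coordinates (pixels, y down)."""

    name: str
    x: float
    y: float

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise LandmarkValidationError(
                f"unknown landmark name {self.name!r}"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise LandmarkValidationError(
                f"non-finite coordinate for landmark {self.name!r}"
            )

    @property
    def side(self) -> str:
        return side_of(self.name)

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class FacialLandmarkSet:
    """All digitized points for one subject in one view.

    ``incisal_edge_points`` and ``lower_lip_points`` are ordered polylines
    (canine-to-canine maxillary incisal edge; upper vermilion border of the
    lower lip) used only by the smile-arc classifier.
    """

    subject_id: str
    view: str
    points: dict[str, Landmark2D] = field(default_factory=dict)
    incisal_edge_points: list[tuple[float, float]] = field(default_factory=list)
    lower_lip_points: list[tuple[float, float]] = field(default_factory=list)
    calibration_mm_per_px: float | None = None

    def __post_init__(self):
        if self.view not in VIEWS:
            raise LandmarkValidationError(f"unknown view {self.view!r}")
        if self.calibration_mm_per_px is not None and not (
            self.calibration_mm_per_px > 0
        ):
            raise LandmarkValidationError(
                "calibration_mm_per_px must be positive"
            )

    def add(self, lm: Landmark2D) -> None:
        if lm.name in self.points:
            raise DuplicateLandmarkError(
                f"duplicate landmark {lm.name!r} for subject "
                f"{self.subject_id!r} view {self.view!r}"
            )
        self.points[lm.name] = lm

    def has(self, name: str) -> bool:
        return name in self.points

    def xy(self, name: str) -> tuple[float, float]:
        try:
            return self.points[name].xy
        except KeyError:
            raise LandmarkValidationError(
                f"landmark {name!r} missing for subject {self.subject_id!r}"
            ) from None


@dataclass(frozen=True)
class ToothMeasurement:
    """Crown dimensions of the maxillary right central incisor.

    ``length`` is the incisocervical crown length and ``width`` the maximum
    mesiodistal width, in the same (arbitrary) units.
    """

    subject_id: str
    length: float
    width: float
    tooth: str = "maxillary right central incisor"

    def __post_init__(self):
        if not (self.length > 0 and self.width > 0):
            raise LandmarkValidationError(
                f"tooth measurements must be positive for subject "
                f"{self.subject_id!r} (length={self.length}, "
                f"width={self.width})"
            )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_for`; never raised, always returned."""

    ok: bool
    missing: tuple[str, ...] = ()
    reasons: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


def validate_for(lset: FacialLandmarkSet, analysis: str) -> ValidationReport:
    """Check that ``lset`` carries everything the given analysis needs.

    ``analysis`` is one of ``proportions`` (golden-ratio distances),
    ``frame`` (beauty frame + RFV/RCV) or ``smile`` (smile-framework
    geometry). Monotone: adding landmarks never invalidates a valid set.
    """
    if analysis not in REQUIRED_LANDMARKS:
        raise ValueError(f"unknown analysis kind {analysis!r}")
    missing = [
        name for name in REQUIRED_LANDMARKS[analysis] if not lset.has(name)
    ]
    reasons: list[str] = []
    if missing:
        reasons.append("missing landmarks: " + ", ".join(missing))
    if analysis in ("proportions", "frame") and not missing:
        xr, yr = lset.xy("LC_R")
        xl, yl = lset.xy("LC_L")
        if math.hypot(xl - xr, yl - yr) == 0.0:
            reasons.append("degenerate canthal axis")
    if analysis == "smile":
        if len(lset.incisal_edge_points) < MIN_CURVE_POINTS:
            reasons.append(
                f"incisal edge needs >= {MIN_CURVE_POINTS} points"
            )
        if len(lset.lower_lip_points) < MIN_CURVE_POINTS:
            reasons.append(f"lower lip needs >= {MIN_CURVE_POINTS} points")
    return ValidationReport(
        ok=not reasons, missing=tuple(missing), reasons=tuple(reasons)
    )


# --------------------------------------------------------------------------
# File I/O — landmark tables
# --------------------------------------------------------------------------

_LANDMARK_COLUMNS = ("subject_id", "view", "landmark", "x", "y")


def _row_to_target(lset: FacialLandmarkSet, landmark: str, x: float, y: float):
    """Dispatch one parsed row into points or an ordered curve list."""
    if landmark.startswith("INC_"):
        lset.incisal_edge_points.append((x, y))
    elif landmark.startswith("LIP_"):
        lset.lower_lip_points.append((x, y))
    else:
        lset.add(Landmark2D(landmark, x, y))


def read_landmark_file(
    path, format: str = "csv", calibration_path=None
) -> list[FacialLandmarkSet]:
    """Read one landmark file into one set per (subject_id, view).

    CSV header is ``subject_id,view,landmark,x,y``; rows named ``INC_1..k``
    / ``LIP_1..m`` populate the ordered incisal-edge and lower-lip curves in
    file order. The JSON dialect holds one object per subject/view with the
    same fields. ``calibration_path`` optionally points to a JSON mapping
    subject_id -> mm-per-pixel scale.
    """
    if format == "csv":
        sets = _read_landmark_csv(path)
    elif format == "json":
        sets = _read_landmark_json(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if calibration_path is not None:
        with open(calibration_path) as fh:
            calib = json.load(fh)
        for lset in sets:
            if lset.subject_id in calib:
                lset.calibration_mm_per_px = float(calib[lset.subject_id])
    return sets


def _read_landmark_csv(path) -> list[FacialLandmarkSet]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in _LANDMARK_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"landmark CSV missing required column {col!r}")
    sets: dict[tuple[str, str], FacialLandmarkSet] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            x = float(row.x)
            y = float(row.y)
        except (TypeError, ValueError):
            raise SchemaError(
                f"non-numeric coordinate at data row {i + 1} "
                f"(subject {row.subject_id!r}, landmark {row.landmark!r})"
            ) from None
        if not (math.isfinite(x) and math.isfinite(y)):
            raise SchemaError(
                f"non-finite coordinate at data row {i + 1} "
                f"(subject {row.subject_id!r}, landmark {row.landmark!r})"
            )
        key = (str(row.subject_id), str(row.view))
        lset = sets.get(key)
        if lset is None:
            lset = FacialLandmarkSet(subject_id=key[0], view=key[1])
            sets[key] = lset
        _row_to_target(lset, str(row.landmark), x, y)
    return list(sets.values())


def _read_landmark_json(path) -> list[FacialLandmarkSet]:
    with open(path) as fh:
        data = json.load(fh)
    sets = []
    for obj in data:
        for key in ("subject_id", "view", "points"):
            if key not in obj:
                raise SchemaError(f"landmark JSON object missing {key!r}")
        lset = FacialLandmarkSet(
            subject_id=str(obj["subject_id"]),
            view=str(obj["view"]),
            calibration_mm_per_px=obj.get("calibration_mm_per_px"),
        )
        for pt in obj["points"]:
            lset.add(Landmark2D(str(pt["name"]), float(pt["x"]), float(pt["y"])))
        for xy in obj.get("incisal_edge_points", []):
            lset.incisal_edge_points.append((float(xy[0]), float(xy[1])))
        for xy in obj.get("lower_lip_points", []):
            lset.lower_lip_points.append((float(xy[0]), float(xy[1])))
        sets.append(lset)
    return sets


def write_landmark_file(sets, path, format: str = "csv") -> None:
    """Inverse of :func:`read_landmark_file` (round-trip lossless)."""
    if format == "csv":
        rows = []
        for lset in sets:
            for lm in lset.points.values():
                rows.append(
                    (lset.subject_id, lset.view, lm.name, repr(lm.x), repr(lm.y))
                )
            for i, (x, y) in enumerate(lset.incisal_edge_points, start=1):
                rows.append((lset.subject_id, lset.view, f"INC_{i}", repr(x), repr(y)))
            for i, (x, y) in enumerate(lset.lower_lip_points, start=1):
                rows.append((lset.subject_id, lset.view, f"LIP_{i}", repr(x), repr(y)))
        pd.DataFrame(rows, columns=_LANDMARK_COLUMNS).to_csv(path, index=False)
    elif format == "json":
        data = []
        for lset in sets:
            obj = {
                "subject_id": lset.subject_id,
                "view": lset.view,
                "points": [
                    {"name": lm.name, "x": lm.x, "y": lm.y}
                    for lm in lset.points.values()
                ],
                "incisal_edge_points": [list(p) for p in lset.incisal_edge_points],
                "lower_lip_points": [list(p) for p in lset.lower_lip_points],
            }
            if lset.calibration_mm_per_px is not None:
                obj["calibration_mm_per_px"] = lset.calibration_mm_per_px
            data.append(obj)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


# --------------------------------------------------------------------------
# File I/O — companion tables
# --------------------------------------------------------------------------


def read_tooth_file(path) -> list[ToothMeasurement]:
    """Read the tooth CSV (``subject_id,length,width``)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "length", "width"):
        if col not in df.columns:
            raise SchemaError(f"tooth CSV missing required column {col!r}")
    return [
        ToothMeasurement(str(r.subject_id), float(r.length), float(r.width))
        for r in df.itertuples(index=False)
    ]


def read_demographics_file(path) -> pd.DataFrame:
    """Read the demographics CSV (``subject_id,sex,age``)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    for col in ("subject_id", "sex"):
        if col not in df.columns:
            raise SchemaError(
                f"demographics CSV missing required column {col!r}"
            )
    bad = set(df["sex"]) - {"female", "male"}
    if bad:
        raise SchemaError(f"unknown sex values {sorted(bad)!r}")
    return df


def read_smile_observations_file(path) -> pd.DataFrame:
    """Read per-subject smile observations.

    Columns: ``subject_id`` — key; ``exposure_fraction`` — visible fraction
    of the maxillary central clinical crown; ``gingival_display`` — one of
    continuous_band / papilla_only / none; ``last_visible_tooth`` — FDI
    tooth-type digit 4..7 of the most posterior tooth shown when smiling.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    needed = (
        "subject_id", "exposure_fraction", "gingival_display",
        "last_visible_tooth",
    )
    for col in needed:
        if col not in df.columns:
            raise SchemaError(
                f"smile observations CSV missing required column {col!r}"
            )
    return df
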