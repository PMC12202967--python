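"""Synthetic landmark cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without photographs:

* midline landmark horizontal offsets in the smile view are drawn as
  ``Normal(rfv_mean * F, rfv_sd * F)`` (truncated at +/- 4 SD) around the
  facial midline, per sex — so the pipeline-recovered RFV distribution has
  the configured mean and SD by construction;
* rest-view vertical/transverse positions are drawn around a template
  calibrated by least squares to the target facial-proportion ratios;
* categorical smile attributes are drawn from sex-specific multinomials and
  realized geometrically so that the default classifiers recover the drawn
  class (curvature signs, lip-corner offsets, exposure fractions, crown
  quotients are all placed inside the drawn class's region);
* a per-view similarity transform (head roll, scale, translation) and
  i.i.d. pixel noise are applied last; the two external canthi anchor the
  frame and are therefore pinned to the template (their digitization error
  is represented by the global pixel-noise term only).

Ground truth records the drawn values and the pre-transform coordinates;
with zero noise and the identity transform the pipeline reproduces it.
Randomness: one global seed; subject ``i`` uses an independent stream
seeded by ``(seed, i)`` so changing ``n`` never reshuffles earlier subjects.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CalibrationError
from .landmark_model import (
    FacialLandmarkSet,
    Landmark2D,
    ToothMeasurement,
    write_landmark_file,
)
from .facial_proportions import RATIO_DEFINITIONS, VERTICAL_RATIOS

# --------------------------------------------------------------------------
# Study-condition defaults (cohort of 637: 350 females, 287 males)
# --------------------------------------------------------------------------

N_FEMALE = 350
N_MALE = 287
N_TOTAL = N_FEMALE + N_MALE

#: Per-sex RFV means and SDs for the five midline landmarks.
RFV_MEANS = {
    "female": {"rfv1": 0.9994, "rfv2": 0.9950, "rfv3": 0.9912,
               "rfv4": 0.9853, "rfv5": 0.9910},
    "male": {"rfv1": 0.9943, "rfv2": 1.0007, "rfv3": 0.9957,
             "rfv4": 0.9844, "rfv5": 0.9937},
}
RFV_SDS = {
    "female": {"rfv1": 0.0888, "rfv2": 0.08887, "rfv3": 0.07960,
               "rfv4": 0.09340, "rfv5": 0.08309},
    "male": {"rfv1": 0.0755, "rfv2": 0.03707, "rfv3": 0.03851,
             "rfv4": 0.07767, "rfv5": 0.03986},
}

#: Pooled-cohort RFV means (reference values for hierarchy checks).
RFV_MEANS_TOTAL = {"rfv1": 0.9981, "rfv2": 0.9964, "rfv3": 0.9924,
                   "rfv4": 0.9851, "rfv5": 0.9917}

#: Per-sex facial-proportion ratio means (calibration targets).
RATIO_MEANS = {
    "female": {
        "TR-ME:LC-ME": 1.69, "LC-ME:TR-LC": 1.45, "TR-LN:LN-ME": 1.53,
        "LN-ME:LC-LN": 2.05, "LC-CH:CH-ME": 1.53, "LC-LN:LN-CH": 1.25,
        "CH-ME:LN-CH": 1.47,
        "CH(r-l):LN(r-l)": 1.47, "LC(r-l):CH(r-l)": 1.78,
        "TS(r-l):LC(r-l)": 1.54,
    },
    "male": {
        "TR-ME:LC-ME": 1.63, "LC-ME:TR-LC": 1.59, "TR-LN:LN-ME": 1.35,
        "LN-ME:LC-LN": 2.15, "LC-CH:CH-ME": 1.40, "LC-LN:LN-CH": 1.13,
        "CH-ME:LN-CH": 1.54,
        "CH(r-l):LN(r-l)": 1.46, "LC(r-l):CH(r-l)": 1.66,
        "TS(r-l):LC(r-l)": 1.51,
    },
}

#: Per-sex smile-framework category probabilities (from per-sex counts).
CATEGORY_COUNTS = {
    "female": {
        "arc": {"consonant": 291, "non_consonant": 59},
        "lip_curvature": {"up": 185, "straight": 101, "down": 64},
        "smile_line": {"high": 94, "medium": 196, "low": 60},
        "smile_width": {"first_premolar": 34, "second_premolar": 141,
                        "first_molar": 167, "second_molar": 8},
        "tooth_shape": {"triangular": 8, "oval": 129, "square": 213},
    },
    "male": {
        "arc": {"consonant": 234, "non_consonant": 53},
        "lip_curvature": {"up": 161, "straight": 73, "down": 53},
        "smile_line": {"high": 66, "medium": 185, "low": 36},
        "smile_width": {"first_premolar": 33, "second_premolar": 86,
                        "first_molar": 155, "second_molar": 13},
        "tooth_shape": {"triangular": 20, "oval": 129, "square": 138},
    },
}

#: Per-sex crown width-to-length ratio mean and SD.
WL_MEAN = {"female": 1.1780, "male": 1.2029}
WL_SD = {"female": 0.12939, "male": 0.17026}

#: Crown-length distribution (units arbitrary; the pipeline is quotient-only).
CROWN_LENGTH_MEAN = 100.72
CROWN_LENGTH_SD = 8.0

#: Width/length intervals implied by the DP% shape classes
#: (DP% = length/width * 100; triangular < 43, oval 43..57, square > 57).
WL_CLASS_INTERVALS = {
    "square": (100.0 / 90.0, 100.0 / 57.0),
    "oval": (100.0 / 57.0, 100.0 / 43.0),
    "triangular": (100.0 / 43.0, 100.0 / 35.0),
}

#: Geometric realization constants (fractions of frame height or F).
LIP_DELTA_FRAC = 0.05       # |Delta| for up/down lip curvature
ARC_CURVATURE = 3e-3        # px^-1 quadratic coefficient magnitude
CURVE_HALF_SPAN_FRAC = 0.3  # incisal/lip curve half-span as fraction of F
N_CURVE_POINTS = 7

_TRUNC_SD = 4.0  # continuous draws truncated at +/- 4 SD


@dataclass(frozen=True)
class CohortParameters:
    """Everything the generator needs; defaults are the study conditions."""

    n_subjects: int = N_TOTAL
    sex_proportion_female: float = N_FEMALE / N_TOTAL
    rfv_means: dict = field(default_factory=lambda: RFV_MEANS)
    rfv_sds: dict = field(default_factory=lambda: RFV_SDS)
    ratio_targets: dict = field(default_factory=lambda: RATIO_MEANS)
    category_probs: dict = field(default_factory=dict)  # filled in __post_init__
    wl_mean: dict = field(default_factory=lambda: WL_MEAN)
    wl_sd: dict = field(default_factory=lambda: WL_SD)
    #: outer inter-canthal distance in pixels; a power of two keeps the
    #: zero-noise round trip u -> u/F bit-exact
    intercanthal_width: float = 512.0
    #: full-face height (TR-ME) in pixels; ~2x the inter-canthal width
    face_height: float = 1024.0
    vertical_jitter_sd: float = 2.5
    transverse_jitter_sd: float = 2.5
    roll_range_deg: float = 5.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    translation_range: float = 200.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.category_probs:
            probs = {
                sex: {
                    attr: _normalize(counts)
                    for attr, counts in by_attr.items()
                }
                for sex, by_attr in CATEGORY_COUNTS.items()
            }
            object.__setattr__(self, "category_probs", probs)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.sex_proportion_female <= 1.0):
            raise ValueError("sex_proportion_female must be in [0, 1]")
        for sex, by_attr in self.category_probs.items():
            for attr, block in by_attr.items():
                s = sum(block.values())
                if any(p < 0 for p in block.values()) or not math.isclose(
                    s, 1.0, rel_tol=0, abs_tol=1e-9
                ):
                    raise ValueError(
                        f"category probabilities for {sex}/{attr} must be "
                        f"non-negative and sum to 1 (sum={s})"
                    )
        for sds in self.rfv_sds.values():
            if any(s < 0 for s in sds.values()):
                raise ValueError("rfv SDs must be >= 0")
        for name in ("vertical_jitter_sd", "transverse_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "CohortParameters":
        return dataclasses.replace(self, **kw)


def _normalize(counts: dict) -> dict:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def default_parameters() -> CohortParameters:
    """The study conditions: printed means/SDs/frequencies, 350:287 split."""
    return CohortParameters()


# --------------------------------------------------------------------------
# Template calibration
# --------------------------------------------------------------------------

_VERTICAL_LANDMARKS = ("TR", "LC", "LN", "CH", "ME")


def calibrate_template(target_ratios: dict) -> tuple[dict, float]:
    """Least-squares vertical positions matching the 7 vertical ratios.

    Returns positions for TR, LC, LN, CH, ME on a 0..1000 axis (TR and ME
    anchored, fixing translation and global scale — ratios of spans
    determine positions only up to a similarity) and the residual sum of
    squared log-ratio mismatches. The 7 targets over-determine the 3 free
    positions, so a nonzero residual is expected for real-world targets.
    """
    targets = {name: float(target_ratios[name]) for name in VERTICAL_RATIOS}
    if any(t <= 0 for t in targets.values()):
        raise CalibrationError("ratio targets must be positive")
    log_t = {k: math.log(v) for k, v in targets.items()}
    me = 1000.0

    def positions(x):
        return {"TR": 0.0, "LC": x[0], "LN": x[1], "CH": x[2], "ME": me}

    def residuals(x):
        pos = positions(x)
        out = []
        for name in VERTICAL_RATIOS:
            num, den = RATIO_DEFINITIONS[name]
            a1, a2 = num.split("_")
            b1, b2 = den.split("_")
            d_num = abs(pos[a1] - pos[a2])
            d_den = abs(pos[b1] - pos[b2])
            if d_num <= 0 or d_den <= 0:
                return [1e6] * len(VERTICAL_RATIOS)
            out.append(math.log(d_num / d_den) - log_t[name])
        return out

    # closed-form starting point from a mutually consistent subset
    r2 = targets["LC-ME:TR-LC"]
    r3 = targets["TR-LN:LN-ME"]
    r5 = targets["LC-CH:CH-ME"]
    lc0 = me / (1.0 + r2)
    ln0 = me * r3 / (1.0 + r3)
    ch0 = (lc0 + r5 * me) / (1.0 + r5)
    x0 = np.array([lc0, ln0, ch0])
    sol = optimize.least_squares(
        residuals, x0, bounds=([1.0] * 3, [999.0] * 3),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise CalibrationError(
            f"template calibration did not converge (residual "
            f"{float(2 * sol.cost):.3g})"
        )
    residual = float(np.sum(np.asarray(residuals(sol.x)) ** 2))
    return positions(sol.x), residual


def calibrate_transverse(target_ratios: dict, lc_rl: float) -> dict:
    """Transverse widths from the 3 transverse ratios, LC(r-l) anchored.

    Exactly solvable: the three targets chain the four widths together."""
    ch = lc_rl / float(target_ratios["LC(r-l):CH(r-l)"])
    ln = ch / float(target_ratios["CH(r-l):LN(r-l)"])
    ts = lc_rl * float(target_ratios["TS(r-l):LC(r-l)"])
    return {"LC_rl": lc_rl, "CH_rl": ch, "LN_rl": ln, "TS_rl": ts}


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its ground truth."""

    landmark_sets: list[FacialLandmarkSet]
    teeth: list[ToothMeasurement]
    demographics: pd.DataFrame
    smile_observations: pd.DataFrame
    ground_truth: dict

    def write(self, outdir) -> dict[str, Path]:
        """Write landmarks/teeth/demographics/smile-observations CSVs and
        ground_truth.json into ``outdir``; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "landmarks": outdir / "landmarks.csv",
            "teeth": outdir / "teeth.csv",
            "demographics": outdir / "demographics.csv",
            "smile_observations": outdir / "smile_observations.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        write_landmark_file(self.landmark_sets, paths["landmarks"], "csv")
        pd.DataFrame(
            [(t.subject_id, repr(t.length), repr(t.width)) for t in self.teeth],
            columns=["subject_id", "length", "width"],
        ).to_csv(paths["teeth"], index=False)
        self.demographics.to_csv(paths["demographics"], index=False)
        self.smile_observations.to_csv(
            paths["smile_observations"], index=False
        )
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        return paths


def _trunc_normal(rng, mean: float, sd: float) -> float:
    """Normal draw truncated at +/- 4 SD (rejection; keeps geometry sane)."""
    if sd == 0.0:
        return mean
    z = rng.standard_normal()
    while abs(z) > _TRUNC_SD:
        z = rng.standard_normal()
    return mean + sd * z


def _draw_category(rng, probs: dict) -> str:
    levels = list(probs)
    p = np.array([probs[l] for l in levels])
    return levels[int(rng.choice(len(levels), p=p / p.sum()))]


def _similarity(rng, params: CohortParameters):
    """One random similarity transform (roll, scale, translation)."""
    theta = math.radians(
        rng.uniform(-params.roll_range_deg, params.roll_range_deg)
    )
    s = rng.uniform(*params.scale_range)
    t = rng.uniform(-params.translation_range, params.translation_range, 2)
    c, si = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -si], [si, c]])
    return s, rot, t


def _apply_transform(coords: dict, transform, rng, noise_sd: float) -> dict:
    s, rot, t = transform
    out = {}
    for name, xy in coords.items():
        p = s * rot @ np.asarray(xy, dtype=float) + t
        if noise_sd > 0:
            p = p + rng.normal(0.0, noise_sd, 2)
        out[name] = (float(p[0]), float(p[1]))
    return out


def _vertical_offsets(template: dict, scale: float) -> dict:
    """Template positions rescaled to pixels, relative to the canthal line."""
    return {
        name: (template[name] - template["LC"]) * scale
        for name in _VERTICAL_LANDMARKS
    }


def generate_cohort(
    params: CohortParameters | None = None,
    n: int | None = None,
    seed: int | None = None,
) -> Cohort:
    """Generate a synthetic cohort of ``n`` subjects with ground truth."""
    if params is None:
        params = default_parameters()
    n = params.n_subjects if n is None else int(n)
    seed = params.seed if seed is None else int(seed)

    width = params.intercanthal_width
    F = width / 2.0
    vscale = params.face_height / 1000.0
    templates = {}
    for sex in ("female", "male"):
        vert, _res = calibrate_template(params.ratio_targets[sex])
        trans = calibrate_transverse(params.ratio_targets[sex], width)
        templates[sex] = (_vertical_offsets(vert, vscale), trans)

    landmark_sets: list[FacialLandmarkSet] = []
    teeth: list[ToothMeasurement] = []
    demo_rows = []
    obs_rows = []
    truth: dict = {}

    for i in range(n):
        rng = np.random.default_rng([seed, i])
        sid = f"S{i:05d}"
        sex = "female" if rng.random() < params.sex_proportion_female else "male"
        voff, twidth = templates[sex]
        sj = params.vertical_jitter_sd
        tj = params.transverse_jitter_sd

        # ---------------- smile view (frame coordinates: x=u, y=v) -------
        rfv = {
            slot: _trunc_normal(
                rng, params.rfv_means[sex][slot], params.rfv_sds[sex][slot]
            )
            for slot in ("rfv1", "rfv2", "rfv3", "rfv4", "rfv5")
        }
        v_ch = voff["CH"]
        height = v_ch + 70.0  # lower boundary through LLI
        ch_half = 0.5 * (twidth["CH_rl"] + rng.normal(0.0, tj) if tj else twidth["CH_rl"])
        mid_u = rfv["rfv5"] * F
        lip_class = _draw_category(rng, params.category_probs[sex]["lip_curvature"])
        delta = {"up": LIP_DELTA_FRAC, "straight": 0.0, "down": -LIP_DELTA_FRAC}[
            lip_class
        ] * height
        smile_pts = {
            "LC_R": (0.0, 0.0),
            "LC_L": (width, 0.0),
            "N": (rfv["rfv1"] * F, -10.0 + (rng.normal(0.0, sj) if sj else 0.0)),
            "PRN": (rfv["rfv2"] * F, voff["LN"] + (rng.normal(0.0, sj) if sj else 0.0)),
            "PHT": (rfv["rfv3"] * F, v_ch - 25.0 + (rng.normal(0.0, sj) if sj else 0.0)),
            "DM": (rfv["rfv4"] * F, v_ch + 5.0 + (rng.normal(0.0, sj) if sj else 0.0)),
            "CH_R": (mid_u - ch_half, v_ch),
            "CH_L": (mid_u + ch_half, v_ch),
            "ULC": (mid_u, v_ch + delta),
            "LLI": (mid_u + (rng.normal(0.0, tj) if tj else 0.0), height),
        }

        arc_class = _draw_category(rng, params.category_probs[sex]["arc"])
        a_lip = -ARC_CURVATURE * (1.0 + 0.3 * rng.random())
        if arc_class == "consonant":
            a_inc = -ARC_CURVATURE * (0.7 + 0.3 * rng.random())
        else:
            a_inc = +0.5 * ARC_CURVATURE  # reverse incisal curve vs curved lip
        half_span = CURVE_HALF_SPAN_FRAC * F
        us = np.linspace(mid_u - half_span, mid_u + half_span, N_CURVE_POINTS)
        inc_pts = [
            (float(u), float(a_inc * (u - mid_u) ** 2 + v_ch + 10.0)) for u in us
        ]
        lip_pts = [
            (float(u), float(a_lip * (u - mid_u) ** 2 + v_ch + 25.0)) for u in us
        ]

        # ---------------- rest view --------------------------------------
        def jx():
            return rng.normal(0.0, tj) if tj else 0.0

        def jy():
            return rng.normal(0.0, sj) if sj else 0.0

        rest_pts = {"LC_R": (0.0, 0.0), "LC_L": (width, 0.0)}
        rest_pts["TR"] = (F + jx(), voff["TR"] + jy())
        rest_pts["ME"] = (F + jx(), voff["ME"] + jy())
        for stem, v_stem in (("LN", voff["LN"]), ("CH", voff["CH"]),
                             ("TS", -40.0)):
            half = twidth[f"{stem}_rl"] / 2.0
            rest_pts[f"{stem}_R"] = (F - half + jx(), v_stem + jy())
            rest_pts[f"{stem}_L"] = (F + half + jx(), v_stem + jy())

        # ---------------- categorical observations & tooth ---------------
        line_class = _draw_category(rng, params.category_probs[sex]["smile_line"])
        if line_class == "high":
            exposure = rng.uniform(1.0, 1.3)
            gingiva = "continuous_band"
        elif line_class == "medium":
            exposure = rng.uniform(0.75, 0.999)
            gingiva = "papilla_only"
        else:
            exposure = rng.uniform(0.3, 0.749)
            gingiva = "none"
        width_class = _draw_category(rng, params.category_probs[sex]["smile_width"])
        tooth_code = {"first_premolar": 4, "second_premolar": 5,
                      "first_molar": 6, "second_molar": 7}[width_class]

        shape_class = _draw_category(rng, params.category_probs[sex]["tooth_shape"])
        lo, hi = WL_CLASS_INTERVALS[shape_class]
        mu, sd = params.wl_mean[sex], params.wl_sd[sex]
        wl = float(stats.truncnorm.rvs(
            (lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd, random_state=rng
        ))
        length = abs(_trunc_normal(rng, CROWN_LENGTH_MEAN, CROWN_LENGTH_SD))
        tooth_width = wl * length

        # ---------------- transform + noise -------------------------------
        tr_smile = _similarity(rng, params)
        tr_rest = _similarity(rng, params)
        smile_img = _apply_transform(smile_pts, tr_smile, rng, params.noise_sd)
        curve_img = _apply_transform(
            {f"INC_{k}": p for k, p in enumerate(inc_pts)}
            | {f"LIP_{k}": p for k, p in enumerate(lip_pts)},
            tr_smile, rng, params.noise_sd,
        )
        rest_img = _apply_transform(rest_pts, tr_rest, rng, params.noise_sd)

        smile_set = FacialLandmarkSet(subject_id=sid, view="frontal_smile")
        for name, xy in smile_img.items():
            smile_set.add(Landmark2D(name, *xy))
        for k in range(N_CURVE_POINTS):
            smile_set.incisal_edge_points.append(curve_img[f"INC_{k}"])
        for k in range(N_CURVE_POINTS):
            smile_set.lower_lip_points.append(curve_img[f"LIP_{k}"])
        rest_set = FacialLandmarkSet(subject_id=sid, view="frontal_rest")
        for name, xy in rest_img.items():
            rest_set.add(Landmark2D(name, *xy))
        landmark_sets.extend([rest_set, smile_set])
        teeth.append(ToothMeasurement(sid, length=length, width=tooth_width))
        demo_rows.append((sid, sex, int(rng.integers(18, 41))))
        obs_rows.append((sid, exposure, gingiva, tooth_code))

        # ---------------- ground truth ------------------------------------
        true_ratios = _true_ratios(rest_pts)
        truth[sid] = {
            "sex": sex,
            "rfv": rfv,
            "rcv": {f"rcv{k}": rfv[f"rfv{k}"] / rfv["rfv5"] for k in range(1, 5)},
            "ratios": true_ratios,
            "arc": arc_class,
            "lip_curvature": lip_class,
            "smile_line": line_class,
            "smile_width": width_class,
            "tooth_shape": shape_class,
            "wl_ratio": wl,
            "pre_transform": {
                "frontal_smile": {k: list(v) for k, v in smile_pts.items()},
                "frontal_rest": {k: list(v) for k, v in rest_pts.items()},
            },
        }

    demographics = pd.DataFrame(demo_rows, columns=["subject_id", "sex", "age"])
    smile_obs = pd.DataFrame(
        obs_rows,
        columns=["subject_id", "exposure_fraction", "gingival_display",
                 "last_visible_tooth"],
    )
    return Cohort(
        landmark_sets=landmark_sets, teeth=teeth, demographics=demographics,
        smile_observations=smile_obs, ground_truth=truth,
    )


def _true_ratios(rest_pts: dict) -> dict:
    """Ratios implied by the pre-transform rest-view coordinates.

    Pre-transform coordinates are axis-aligned (the canthi sit on y = 0), so
    vertical spans are y-differences of (pair-mean) positions and transverse
    spans are point-to-point distances.
    """
    y = {
        "TR": rest_pts["TR"][1],
        "ME": rest_pts["ME"][1],
        "LC": 0.5 * (rest_pts["LC_R"][1] + rest_pts["LC_L"][1]),
        "LN": 0.5 * (rest_pts["LN_R"][1] + rest_pts["LN_L"][1]),
        "CH": 0.5 * (rest_pts["CH_R"][1] + rest_pts["CH_L"][1]),
    }
    d = {}
    for a in ("TR", "LC", "LN", "CH", "ME"):
        for b in ("TR", "LC", "LN", "CH", "ME"):
            d[f"{a}_{b}"] = abs(y[a] - y[b])
    for stem in ("CH", "LC", "TS", "LN"):
        r = np.asarray(rest_pts[f"{stem}_R"])
        l = np.asarray(rest_pts[f"{stem}_L"])
        d[f"{stem}_rl"] = float(np.hypot(*(l - r)))
    return {
        name: d[num] / d[den]
        for name, (num, den) in RATIO_DEFINITIONS.items()
    }
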