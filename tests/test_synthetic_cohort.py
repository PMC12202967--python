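"""Generator defaults, template calibration, and ground-truth consistency."""

import json

import numpy as np
import pytest

from smileframe import (
    CohortParameters,
    analyze_cohort,
    calibrate_template,
    calibrate_transverse,
    default_parameters,
    generate_cohort,
)
from smileframe.facial_proportions import RATIO_DEFINITIONS, VERTICAL_RATIOS
from smileframe.synthetic_cohort import RFV_MEANS_TOTAL


def quiet_params():
    """Defaults with transforms and noise off (identity geometry)."""
    return default_parameters().replace(
        noise_sd=0.0, roll_range_deg=0.0, scale_range=(1.0, 1.0),
        translation_range=0.0,
    )


def ratios_from_positions(pos):
    d = {}
    for name in ("TR", "LC", "LN", "CH", "ME"):
        for other in ("TR", "LC", "LN", "CH", "ME"):
            d[f"{name}_{other}"] = abs(pos[name] - pos[other])
    return {
        name: d[num] / d[den]
        for name, (num, den) in RATIO_DEFINITIONS.items()
        if name in VERTICAL_RATIOS
    }


# ---------------------------- defaults -------------------------------------


def test_default_rfv_means_match_study_values():
    p = default_parameters()
    assert p.rfv_means["female"]["rfv1"] == 0.9994
    assert p.rfv_means["male"]["rfv4"] == 0.9844
    assert RFV_MEANS_TOTAL["rfv1"] == 0.9981


def test_default_category_probs_normalized():
    p = default_parameters()
    for sex, blocks in p.category_probs.items():
        for attr, probs in blocks.items():
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in probs.values())
    assert p.category_probs["female"]["smile_width"]["first_molar"] == (
        pytest.approx(167 / 350)
    )
    assert p.category_probs["male"]["smile_width"]["first_molar"] == (
        pytest.approx(155 / 287)
    )


def test_default_sex_split():
    p = default_parameters()
    assert p.n_subjects == 637
    assert p.sex_proportion_female == pytest.approx(350 / 637)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        default_parameters().replace(n_subjects=0)
    with pytest.raises(ValueError):
        default_parameters().replace(noise_sd=-1.0)
    with pytest.raises(ValueError):
        default_parameters().replace(
            category_probs={"female": {"arc": {"consonant": 0.5}},
                            "male": {"arc": {"consonant": 1.0}}}
        )


# ---------------------------- calibration ----------------------------------


def test_calibrate_recovers_known_positions():
    truth = {"TR": 0.0, "LC": 350.0, "LN": 600.0, "CH": 780.0, "ME": 1000.0}
    targets = ratios_from_positions(truth)
    pos, residual = calibrate_template(targets)
    assert residual < 1e-10
    for name, v in truth.items():
        assert pos[name] == pytest.approx(v, abs=1e-4)


def test_calibrate_recovers_up_to_scale():
    truth = {"TR": 0.0, "LC": 175.0, "LN": 300.0, "CH": 390.0, "ME": 500.0}
    targets = ratios_from_positions(truth)
    pos, residual = calibrate_template(targets)
    assert residual < 1e-10
    for name, v in truth.items():
        assert pos[name] == pytest.approx(2.0 * v, abs=1e-3)


def test_calibrate_study_targets_overdetermined():
    p = default_parameters()
    pos, residual = calibrate_template(p.ratio_targets["female"])
    assert 0 < residual < 0.05  # close but not exact: 7 targets, 3 unknowns
    assert pos["TR"] < pos["LC"] < pos["LN"] < pos["CH"] < pos["ME"]


def test_calibrate_transverse_exactly_invertible():
    targets = {"CH(r-l):LN(r-l)": 1.47, "LC(r-l):CH(r-l)": 1.78,
               "TS(r-l):LC(r-l)": 1.54}
    w = calibrate_transverse(targets, lc_rl=512.0)
    assert w["LC_rl"] / w["CH_rl"] == pytest.approx(1.78, rel=1e-12)
    assert w["CH_rl"] / w["LN_rl"] == pytest.approx(1.47, rel=1e-12)
    assert w["TS_rl"] / w["LC_rl"] == pytest.approx(1.54, rel=1e-12)


# ---------------------------- generation -----------------------------------


def test_zero_spread_recovers_means_to_float_precision():
    p = quiet_params().replace(
        rfv_sds={s: {k: 0.0 for k in v} for s, v in
                 default_parameters().rfv_sds.items()},
        vertical_jitter_sd=0.0, transverse_jitter_sd=0.0,
    )
    cohort = generate_cohort(p, n=10, seed=4)
    rfv_df, _, _, _ = analyze_cohort(
        cohort.landmark_sets, cohort.teeth, cohort.smile_observations
    )
    demo = cohort.demographics.set_index("subject_id")["sex"]
    for _, row in rfv_df.iterrows():
        sex = demo[row["subject_id"]]
        for k in range(1, 5):
            # midline landmarks sit at u = mean * F with F a power of two,
            # so the round trip is bit-exact
            assert row[f"rfv{k}"] == p.rfv_means[sex][f"rfv{k}"]
        # the commissure midline goes through a +-half-width round trip
        assert row["rfv5"] == pytest.approx(
            p.rfv_means[sex]["rfv5"], abs=5e-15
        )


def test_same_seed_identical_files(tmp_path):
    p = default_parameters()
    d1, d2 = tmp_path / "a", tmp_path / "b"
    generate_cohort(p, n=8, seed=9).write(d1)
    generate_cohort(p, n=8, seed=9).write(d2)
    for name in ("landmarks.csv", "teeth.csv", "demographics.csv",
                 "smile_observations.csv", "ground_truth.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_prefix_stable_when_n_grows():
    p = default_parameters()
    small = generate_cohort(p, n=5, seed=2)
    large = generate_cohort(p, n=9, seed=2)
    assert json.dumps(small.ground_truth, sort_keys=True) == json.dumps(
        {k: large.ground_truth[k] for k in small.ground_truth}, sort_keys=True
    )


def test_ground_truth_consistency_zero_noise():
    cohort = generate_cohort(quiet_params(), n=25, seed=6)
    rfv_df, ratios_df, smile_df, excl = analyze_cohort(
        cohort.landmark_sets, cohort.teeth, cohort.smile_observations
    )
    assert excl.empty
    gt = cohort.ground_truth
    rfv_df = rfv_df.set_index("subject_id")
    smile_df = smile_df.set_index("subject_id")
    wide = ratios_df.pivot(index="subject_id", columns="ratio", values="value")
    for sid, truth in gt.items():
        for k in range(1, 6):
            assert rfv_df.loc[sid, f"rfv{k}"] == pytest.approx(
                truth["rfv"][f"rfv{k}"], rel=1e-9
            )
        for k in range(1, 5):
            assert rfv_df.loc[sid, f"rcv{k}"] == pytest.approx(
                truth["rcv"][f"rcv{k}"], rel=1e-9
            )
        for name, val in truth["ratios"].items():
            assert wide.loc[sid, name] == pytest.approx(val, rel=1e-9)
        for attr in ("arc", "lip_curvature", "smile_line", "smile_width",
                     "tooth_shape"):
            assert smile_df.loc[sid, attr] == truth[attr]


def test_transform_robustness():
    """Roll/scale/translation (noise off) leave all measurements intact."""
    p = quiet_params().replace(
        roll_range_deg=10.0, scale_range=(0.5, 2.0), translation_range=300.0
    )
    cohort = generate_cohort(p, n=25, seed=6)
    rfv_df, ratios_df, _, _ = analyze_cohort(
        cohort.landmark_sets, cohort.teeth, cohort.smile_observations
    )
    gt = cohort.ground_truth
    rfv_df = rfv_df.set_index("subject_id")
    wide = ratios_df.pivot(index="subject_id", columns="ratio", values="value")
    for sid, truth in gt.items():
        for k in range(1, 6):
            assert rfv_df.loc[sid, f"rfv{k}"] == pytest.approx(
                truth["rfv"][f"rfv{k}"], rel=1e-9
            )
        for name, val in truth["ratios"].items():
            assert wide.loc[sid, name] == pytest.approx(val, rel=1e-9)


def test_rfv_sample_mean_recovery_light():
    """Sample means track the sex-mixture generating means (4 SE guard)."""
    p = default_parameters()
    cohort = generate_cohort(p, n=600, seed=13)
    rfv_df, _, _, _ = analyze_cohort(
        cohort.landmark_sets, cohort.teeth, cohort.smile_observations
    )
    pf = p.sex_proportion_female
    for k in range(1, 6):
        target = (pf * p.rfv_means["female"][f"rfv{k}"]
                  + (1 - pf) * p.rfv_means["male"][f"rfv{k}"])
        col = rfv_df[f"rfv{k}"]
        se = col.std(ddof=1) / np.sqrt(len(col))
        assert abs(col.mean() - target) < 4 * se


def test_truth_wl_realizes_drawn_shape_class():
    cohort = generate_cohort(default_parameters(), n=200, seed=8)
    for truth in cohort.ground_truth.values():
        dp = 100.0 / truth["wl_ratio"]
        if truth["tooth_shape"] == "triangular":
            assert dp < 43
        elif truth["tooth_shape"] == "square":
            assert dp > 57
        else:
            assert 43 <= dp <= 57
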