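"""Descriptive builders, sex tests, correlation and reliability."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from smileframe import (
    DegenerateTableError,
    InsufficientDataError,
    categorical_sex_test,
    continuous_sex_test,
    pearson_correlation,
    summarize_categorical,
    summarize_continuous,
)
from smileframe import test_retest_icc as retest_icc
from smileframe.cohort_stats import _fisher_rxc_pvalue, _mann_whitney_exact


# ---------------------------- categorical ---------------------------------


def test_percent_of_grand_total_printed_counts():
    counts = {"first_molar": 314, "second_premolar": 240,
              "first_premolar": 64, "second_molar": 19}
    summ = summarize_categorical(counts, "smile_width", grand_total=637)
    assert round(summ.percents["first_molar"], 1) == 49.3
    assert round(summ.percents["second_premolar"], 1) == 37.7
    assert round(summ.percents["second_molar"], 1) == 3.0


def test_percent_single_level():
    summ = summarize_categorical({"only": 12}, "attr")
    assert summ.percents["only"] == 100.0


def test_percent_quarters():
    summ = summarize_categorical({"a": 1, "b": 3}, "attr", grand_total=4)
    assert summ.percents == {"a": 25.0, "b": 75.0}


def test_percents_sum_to_hundred_after_rounding():
    rng = np.random.default_rng(11)
    for _ in range(20):
        counts = {f"l{i}": int(c) for i, c in
                  enumerate(rng.integers(1, 400, size=5))}
        summ = summarize_categorical(counts, "attr")
        rounded = sum(round(p, 1) for p in summ.percents.values())
        assert abs(rounded - 100.0) <= 0.2


def test_categorical_from_records_with_sex():
    df = pd.DataFrame({
        "arc": ["consonant"] * 3 + ["non_consonant"] * 1,
        "sex": ["female", "female", "male", "male"],
    })
    summ = summarize_categorical(df, "arc")
    assert summ.counts == {"consonant": 3, "non_consonant": 1}
    assert summ.by_sex_counts["female"] == {"consonant": 2}
    assert summ.by_sex_percents["male"]["consonant"] == 50.0


def test_grand_total_must_be_positive():
    with pytest.raises(InsufficientDataError):
        summarize_categorical({"a": 1}, "attr", grand_total=0)


# ---------------------------- continuous ----------------------------------


def test_mean_sd_basic():
    summ = summarize_continuous([1.0, 2.0, 3.0], "v")
    assert summ.mean == 2.0 and summ.sd == 1.0


def test_sd_constant_zero():
    assert summarize_continuous([5.0] * 10, "v").sd == 0.0


def test_mean_sd_two_pass_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(10, 2, 100)
    summ = summarize_continuous(x, "v")
    mean = sum(x) / len(x)
    sd = (sum((xi - mean) ** 2 for xi in x) / (len(x) - 1)) ** 0.5
    assert summ.mean == pytest.approx(mean, abs=1e-12)
    assert summ.sd == pytest.approx(sd, abs=1e-12)


def test_insufficient_group():
    with pytest.raises(InsufficientDataError):
        summarize_continuous([1.0], "v")


# ---------------------------- chi-square / Fisher --------------------------


def test_chi_square_independence():
    method, stat, p = categorical_sex_test([[10, 10], [10, 10]])
    assert method == "chi_square"
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_chi_square_closed_form():
    # n(ad-bc)^2 / (r1 r2 c1 c2) = 60*300^2/30^4 = 6.6667
    method, stat, _ = categorical_sex_test([[20, 10], [10, 20]])
    assert method == "chi_square"
    assert round(stat, 4) == 6.6667


def test_chi_square_transpose_invariant():
    t = [[12, 7, 5], [3, 9, 14]]
    _, s1, p1 = categorical_sex_test(t)
    _, s2, p2 = categorical_sex_test(np.transpose(t))
    assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)


def test_fisher_rule_triggers_on_small_expected():
    # expected counts 1.5 / 1.5 < 5 in half the cells -> Fisher
    method, stat, p = categorical_sex_test([[1, 9], [2, 8]])
    assert method == "fisher" and stat is None and 0 <= p <= 1


def test_fisher_rxc_matches_r_oracle():
    # frozen from R: fisher.test(matrix(c(2,3,1,4,1,5),nrow=3)) = 0.3019481
    assert _fisher_rxc_pvalue(np.array([[2, 4], [3, 1], [1, 5]])) == (
        pytest.approx(0.3019480519480516, rel=1e-9)
    )
    # fisher.test(matrix(c(1,3,0,2,1,2,0,4,2),nrow=3)) = 0.2503497
    assert _fisher_rxc_pvalue(np.array([[1, 2, 0], [3, 1, 4], [0, 2, 2]])) == (
        pytest.approx(0.2503496503496504, rel=1e-9)
    )


def test_fisher_rxc_reduces_to_scipy_2x2():
    from scipy import stats

    t = np.array([[1, 9], [2, 8]])
    assert _fisher_rxc_pvalue(t) == pytest.approx(
        stats.fisher_exact(t)[1], rel=1e-9
    )


def test_zero_margin_rejected():
    with pytest.raises(DegenerateTableError):
        categorical_sex_test([[0, 0], [5, 6]])


# ---------------------------- Mann-Whitney --------------------------------


def test_mann_whitney_exact_separated():
    u, p = continuous_sex_test([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)


def test_mann_whitney_identical_groups():
    _, p = continuous_sex_test([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_mann_whitney_enumeration_matches_scipy_no_ties():
    from scipy import stats

    a, b = [3.1, 0.2, 5.5, 1.7], [2.2, 4.9, 0.9]
    u, p = _mann_whitney_exact(np.array(a, float), np.array(b, float))
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert u == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_mann_whitney_large_shift_significant():
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 1.0, 200)
    b = rng.normal(1.0, 1.0, 200)
    _, p = continuous_sex_test(a, b)
    assert p < 0.001


def test_mann_whitney_empty_group():
    with pytest.raises(InsufficientDataError):
        continuous_sex_test([], [1.0])


# ---------------------------- Pearson / ICC --------------------------------


def test_pearson_perfect_lines():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r_pos, _ = pearson_correlation(x, 2 * x + 1)
    r_neg, _ = pearson_correlation(x, -x)
    assert r_pos == pytest.approx(1.0, abs=1e-12)
    assert r_neg == pytest.approx(-1.0, abs=1e-12)


def test_pearson_matches_covariance_formula():
    rng = np.random.default_rng(9)
    x = rng.normal(size=50)
    y = 0.4 * x + rng.normal(size=50)
    r, _ = pearson_correlation(x, y)
    oracle = float(
        ((x - x.mean()) * (y - y.mean())).sum()
        / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    )
    assert r == pytest.approx(oracle, abs=1e-12)


def test_pearson_zero_variance():
    with pytest.raises(InsufficientDataError):
        pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_icc_identical_retest_is_one():
    x = [0.99, 1.01, 0.95, 1.04, 1.00]
    assert retest_icc(x, x).icc == pytest.approx(1.0, abs=1e-12)


def test_icc_independent_noise_near_zero():
    rng = np.random.default_rng(21)
    report = retest_icc(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
    assert abs(report.icc) < 0.1


def test_icc_hand_computed_mean_squares():
    """5x2 table checked against ICC(2,1) mean squares computed by hand."""
    m1 = np.array([9.0, 10.0, 12.0, 6.0, 8.0])
    m2 = np.array([10.0, 11.0, 13.0, 7.0, 8.0])
    data = np.column_stack([m1, m2])
    n, k = 5, 2
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((data - grand) ** 2).sum()
        - (n - 1) * msr - (k - 1) * msc
    ) / ((n - 1) * (k - 1))
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert retest_icc(m1, m2).icc == pytest.approx(expected, abs=1e-12)


def test_icc_matches_pingouin():
    rng = np.random.default_rng(0)
    m1 = rng.normal(0, 1, 20)
    m2 = m1 + rng.normal(0, 0.3, 20) + 0.2
    df = pd.DataFrame({
        "subject": list(range(20)) * 2,
        "rater": ["a"] * 20 + ["b"] * 20,
        "score": np.concatenate([m1, m2]),
    })
    ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                             ratings="score")
    ref_icc = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    assert retest_icc(m1, m2).icc == pytest.approx(ref_icc, abs=1e-9)


def test_icc_length_mismatch():
    with pytest.raises(ValueError):
        retest_icc([1.0, 2.0, 3.0], [1.0, 2.0])
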