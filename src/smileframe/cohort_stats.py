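"""Cohort descriptive tables, sex comparisons, correlation and reliability.

Statistical conventions:

* categorical sex differences: Pearson chi-square without continuity
  correction, switching to the Fisher exact test when more than 33% of the
  table's cells have expected counts below five;
* continuous sex differences: two-sided Mann-Whitney U — exact enumeration
  of all group assignments when the pooled sample has at most 12 values
  (ties handled through midranks), normal approximation with tie correction
  otherwise;
* reliability: ICC(2,1), the two-way random-effects, absolute-agreement,
  single-measurement intraclass correlation;
* display rounding: one decimal for percents, two for ratios, four for
  p-values — internal arithmetic is never rounded.

Percentages in category tables use the grand total as denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, InsufficientDataError

#: Expected-count rule: use Fisher when the fraction of cells with expected
#: frequency below five exceeds this.
FISHER_EXPECTED_FRACTION = 0.33
FISHER_EXPECTED_MIN = 5.0

#: Largest pooled sample for which the Mann-Whitney p is enumerated exactly.
MANN_WHITNEY_EXACT_MAX_N = 12

#: Hard cap on the number of contingency tables enumerated by the r x c
#: Fisher test; the rule above only triggers it on sparse tables.
_FISHER_ENUM_CAP = 2_000_000

PERCENT_DECIMALS = 1
RATIO_DECIMALS = 2
P_DECIMALS = 4


@dataclass(frozen=True)
class CategoricalSummary:
    """Counts and grand-total percents for one categorical attribute."""

    attribute: str
    counts: dict[str, int]
    percents: dict[str, float]  # of the grand total, unrounded
    grand_total: int
    by_sex_counts: dict[str, dict[str, int]] | None = None
    by_sex_percents: dict[str, dict[str, float]] | None = None  # within sex
    test_method: str | None = None
    statistic: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class ContinuousSummary:
    """Sample mean and n-1 SD, overall and (optionally) per sex."""

    variable: str
    mean: float
    sd: float
    n: int
    by_sex: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    p_value: float | None = None


@dataclass(frozen=True)
class ReliabilityReport:
    """Test-retest reliability of one item pair."""

    item_pair: str
    icc: float
    n: int


# --------------------------------------------------------------------------
# Descriptive summaries
# --------------------------------------------------------------------------


def summarize_categorical(
    data, attribute: str, grand_total: int | None = None, levels=None
) -> CategoricalSummary:
    """Counts and percents-of-grand-total for one attribute.

    ``data`` is either a mapping level -> count or a DataFrame of per-subject
    records holding an ``attribute`` column (and optionally ``sex``).
    ``grand_total`` defaults to the sum of counts; passing it explicitly
    supports tables whose rows do not exhaust the cohort.
    """
    by_sex_counts = by_sex_percents = None
    if isinstance(data, pd.DataFrame):
        counts_ser = data[attribute].value_counts()
        counts = {str(k): int(v) for k, v in counts_ser.items()}
        if "sex" in data.columns:
            by_sex_counts = {}
            by_sex_percents = {}
            for sex, sub in data.groupby("sex"):
                c = {str(k): int(v) for k, v in sub[attribute].value_counts().items()}
                tot = len(sub)
                by_sex_counts[str(sex)] = c
                by_sex_percents[str(sex)] = {
                    k: v / tot * 100.0 for k, v in c.items()
                }
    else:
        counts = {str(k): int(v) for k, v in dict(data).items()}
    if levels is not None:
        counts = {lvl: counts.get(lvl, 0) for lvl in levels}
    if grand_total is None:
        grand_total = sum(counts.values())
    if grand_total <= 0:
        raise InsufficientDataError("grand total must be positive")
    percents = {k: v / grand_total * 100.0 for k, v in counts.items()}
    return CategoricalSummary(
        attribute=attribute, counts=counts, percents=percents,
        grand_total=int(grand_total),
        by_sex_counts=by_sex_counts, by_sex_percents=by_sex_percents,
    )


def _mean_sd(values) -> tuple[float, float, int]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 values per group, got {arr.size}"
        )
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def summarize_continuous(
    records, variable: str, by_sex: bool = False
) -> ContinuousSummary:
    """Sample mean and n-1 SD of ``variable``, optionally stratified by sex.

    ``records`` is a DataFrame (columns ``variable`` and, if stratifying,
    ``sex``) or a plain value sequence.
    """
    if isinstance(records, pd.DataFrame):
        values = records[variable].to_numpy(dtype=float)
    else:
        values = np.asarray(list(records), dtype=float)
        by_sex = False
    mean, sd, n = _mean_sd(values)
    per_sex: dict[str, tuple[float, float, int]] = {}
    if by_sex:
        for sex, sub in records.groupby("sex"):
            per_sex[str(sex)] = _mean_sd(sub[variable].to_numpy(dtype=float))
    return ContinuousSummary(
        variable=variable, mean=mean, sd=sd, n=n, by_sex=per_sex
    )


# --------------------------------------------------------------------------
# Hypothesis tests
# --------------------------------------------------------------------------


def _fisher_rxc_pvalue(table: np.ndarray) -> float:
    """Exact Fisher p for an r x c table by full enumeration.

    Sums the conditional (fixed-margin multivariate hypergeometric)
    probability of every table at most as probable as the observed one.
    Intended for the sparse tables the expected-count rule routes here.
    """
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    lg = math.lgamma
    log_const = (
        sum(lg(r + 1) for r in row_sums)
        + sum(lg(c + 1) for c in col_sums)
        - lg(n + 1)
    )

    def log_prob(cells) -> float:
        return log_const - sum(lg(v + 1) for v in cells)

    p_obs = log_prob(table.ravel())
    rows = len(row_sums)
    total = 0.0
    count = 0

    def recurse(row_idx: int, remaining_cols, acc_logp: float):
        nonlocal total, count
        if row_idx == rows - 1:
            # last row forced by the column margins
            if min(remaining_cols) < 0:
                return
            logp = acc_logp - sum(lg(v + 1) for v in remaining_cols)
            count += 1
            if count > _FISHER_ENUM_CAP:
                raise InsufficientDataError(
                    "Fisher r x c enumeration too large for this table"
                )
            if logp <= p_obs + 1e-10:
                total += math.exp(logp)
            return
        r = int(row_sums[row_idx])
        ncols = len(remaining_cols)

        def fill(col_idx: int, left: int, cells):
            if col_idx == ncols - 1:
                if left <= remaining_cols[col_idx]:
                    recurse(
                        row_idx + 1,
                        tuple(
                            remaining_cols[j] - (cells + (left,))[j]
                            for j in range(ncols)
                        ),
                        acc_logp - sum(lg(v + 1) for v in cells + (left,)),
                    )
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                fill(col_idx + 1, left - v, cells + (v,))

        fill(0, r, ())

    recurse(0, tuple(int(c) for c in col_sums), log_const)
    return min(total, 1.0)


def categorical_sex_test(table) -> tuple[str, float | None, float]:
    """Chi-square or Fisher exact test for an r x c count table.

    Fisher is used when more than 33% of cells have expected counts below 5;
    otherwise a Pearson chi-square without continuity correction. Returns
    ``(method, statistic or None, p)``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2-D array of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    frac_small = float((expected < FISHER_EXPECTED_MIN).mean())
    if frac_small > FISHER_EXPECTED_FRACTION:
        ti = t.astype(int)
        if ti.shape == (2, 2):
            _, p = stats.fisher_exact(ti, alternative="two-sided")
        else:
            p = _fisher_rxc_pvalue(ti)
        return "fisher", None, float(p)
    chi2, p, _dof, _exp = stats.chi2_contingency(t, correction=False)
    return "chi_square", float(chi2), float(p)


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks handle ties
    n1, n2 = len(a), len(b)
    u_from_ranks = lambda rsum: rsum - n1 * (n1 + 1) / 2.0
    u_obs = u_from_ranks(ranks[:n1].sum())
    stat_obs = min(u_obs, n1 * n2 - u_obs)
    hits = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = u_from_ranks(ranks[list(idx)].sum())
        if min(u, n1 * n2 - u) <= stat_obs + 1e-9:
            hits += 1
        total += 1
    return float(u_obs), hits / total


def continuous_sex_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two value groups.

    Returns ``(U, p)`` where U counts (a > b) pairs (ties half). Exact
    enumeration when the pooled n is at most 12, else the normal
    approximation with tie correction (no continuity correction).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if a.size + b.size <= MANN_WHITNEY_EXACT_MAX_N:
        return _mann_whitney_exact(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic",
        use_continuity=False,
    )
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 pairs for a correlation")
    if x.std() == 0.0 or y.std() == 0.0:
        raise InsufficientDataError(
            "correlation undefined: zero variance in an input"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def test_retest_icc(
    measure_1, measure_2, item_pair: str = ""
) -> ReliabilityReport:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the n x 2 table whose
    columns are the first and second measurement sessions.
    """
    m1 = np.asarray(list(measure_1), dtype=float)
    m2 = np.asarray(list(measure_2), dtype=float)
    if m1.size != m2.size:
        raise ValueError("measurement vectors must have equal length")
    n = m1.size
    if n < 3:
        raise InsufficientDataError("need >= 3 paired measurements")
    data = np.column_stack([m1, m2])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise InsufficientDataError(
            "ICC undefined: no variance in the measurements"
        )
    icc = (msr - mse) / denom
    return ReliabilityReport(item_pair=item_pair, icc=float(icc), n=int(n))


# --------------------------------------------------------------------------
# Report builders (Tables 1/3/5-shaped)
# --------------------------------------------------------------------------


def build_continuous_table(
    df: pd.DataFrame, variables, golden_reference: float | None = None
) -> pd.DataFrame:
    """Long-format summary of continuous variables with per-sex columns.

    One row per variable: total and per-sex mean/SD plus the Mann-Whitney p.
    When ``golden_reference`` is given, per-sex percent-of-reference columns
    are added (computed from the unrounded means).
    """
    rows = []
    has_sex = "sex" in df.columns and df["sex"].nunique() > 1
    for var in variables:
        summ = summarize_continuous(df, var, by_sex="sex" in df.columns)
        row: dict = {
            "variable": var,
            "mean": summ.mean, "sd": summ.sd, "n": summ.n,
        }
        for sex in ("female", "male"):
            if sex in summ.by_sex:
                m, s, n = summ.by_sex[sex]
                row[f"{sex}_mean"] = m
                row[f"{sex}_sd"] = s
                row[f"{sex}_n"] = n
                if golden_reference is not None:
                    row[f"{sex}_golden_percent"] = m / golden_reference * 100.0
            else:
                row[f"{sex}_mean"] = row[f"{sex}_sd"] = np.nan
                row[f"{sex}_n"] = 0
                if golden_reference is not None:
                    row[f"{sex}_golden_percent"] = np.nan
        if golden_reference is not None:
            row["golden_percent"] = summ.mean / golden_reference * 100.0
        if has_sex:
            groups = {
                sex: sub[var].to_numpy(dtype=float)
                for sex, sub in df.groupby("sex")
            }
            _, p = continuous_sex_test(
                groups.get("female", []), groups.get("male", [])
            )
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_categorical_table(
    df: pd.DataFrame, attributes: dict[str, tuple[str, ...]]
) -> pd.DataFrame:
    """Smile-framework-style frequency table with per-sex columns.

    ``attributes`` maps attribute name -> ordered level tuple. Percents of
    the grand total for the pooled column, within-sex percents for the sex
    columns; the sex-association p comes from the chi-square/Fisher rule
    applied to the level x sex count table.
    """
    rows = []
    grand_total = len(df)
    has_sex = "sex" in df.columns and df["sex"].nunique() > 1
    for attr, levels in attributes.items():
        summ = summarize_categorical(df, attr, grand_total, levels=levels)
        p_value = np.nan
        method = None
        if has_sex:
            table = np.array([
                [
                    int(((df[attr] == lvl) & (df["sex"] == sex)).sum())
                    for sex in ("female", "male")
                ]
                for lvl in levels
            ])
            table = table[table.sum(axis=1) > 0]  # drop empty levels
            if table.shape[0] >= 2:
                method, _stat, p_value = categorical_sex_test(table)
        for lvl in levels:
            row = {
                "attribute": attr,
                "level": lvl,
                "n": summ.counts.get(lvl, 0),
                "percent": summ.percents.get(lvl, 0.0),
                "test": method,
                "p_value": p_value,
            }
            for sex in ("female", "male"):
                if summ.by_sex_counts and sex in summ.by_sex_counts:
                    row[f"{sex}_n"] = summ.by_sex_counts[sex].get(lvl, 0)
                    row[f"{sex}_percent"] = summ.by_sex_percents[sex].get(lvl, 0.0)
                else:
                    row[f"{sex}_n"] = 0
                    row[f"{sex}_percent"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def round_for_display(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the display-rounding convention to a report table copy."""
    out = df.copy()
    for col in out.columns:
        if col.endswith("percent"):
            out[col] = out[col].round(PERCENT_DECIMALS)
        elif col.endswith(("mean", "sd")) or col in ("mean", "sd"):
            out[col] = out[col].round(RATIO_DECIMALS)
        elif col.endswith("p_value"):
            out[col] = out[col].round(P_DECIMALS)
    return out
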