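"""Normality-gated summaries and left-vs-right cohort comparisons.

Continuous variables are tested for normality (Shapiro-Wilk at alpha=0.05)
and summarized as mean +/- SD when consistent with normality, otherwise as
median (Q1-Q3). Between-hemisphere comparisons use the two-sided Wilcoxon
rank-sum test for continuous variables and the chi-square test for
categorical ones, with per-variable complete-case handling so denominators
can differ across rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass(frozen=True)
class ContinuousSummary:
    form: str  # "mean_sd" | "median_iqr"
    location: float  # mean or median
    spread: tuple[float, float]  # (sd, sd) or (q1, q3)
    n: int
    shapiro_p: float | None

    def __str__(self) -> str:
        if self.form == "mean_sd":
            return f"{self.location:.2f} ± {self.spread[0]:.2f}"
        return f"{self.location:.2f} ({self.spread[0]:.2f}–{self.spread[1]:.2f})"


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary_left: str
    summary_right: str
    test: str  # "wilcoxon" | "chi-square"
    p_value: float
    significant: bool


def summarize_continuous(values) -> ContinuousSummary:
    """Summarize a numeric vector, choosing the form by Shapiro-Wilk.

    Mean +/- SD when the normality test does not reject at alpha=0.05,
    median with type-7 (linear interpolation) quartiles otherwise. Constant
    vectors are degenerate for the test and fall to the median form with a
    warning. Requires >= 3 non-missing values.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(
            f"need >= 3 non-missing values for Shapiro-Wilk, got {len(x)}"
        )
    if np.ptp(x) == 0:
        warnings.warn("constant vector: normality undefined, reporting median(IQR)")
        return ContinuousSummary(
            "median_iqr", float(x[0]), (float(x[0]), float(x[0])), len(x), None
        )
    p = float(stats.shapiro(x).pvalue)
    if p >= ALPHA:
        return ContinuousSummary(
            "mean_sd", float(x.mean()), (float(x.std(ddof=1)),) * 2, len(x), p
        )
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # type-7 linear interpolation
    return ContinuousSummary("median_iqr", float(med), (float(q1), float(q3)), len(x), p)


def _ranksum_p(left: np.ndarray, right: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when both groups are small and
    untied, normal approximation with tie correction otherwise."""
    has_ties = len(np.unique(np.concatenate([left, right]))) < len(left) + len(right)
    method = "exact" if (max(len(left), len(right)) <= 25 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(left, right, alternative="two-sided", method=method).pvalue
    )


def compare_groups(
    left, right, kind: str, variable: str = "", correction: bool = False
) -> GroupComparison:
    """Compare one variable between hemisphere groups.

    ``kind='continuous'``: two-sided Wilcoxon rank-sum on the raw values,
    each side summarized per ``summarize_continuous``. ``kind='categorical'``:
    chi-square on the levels-by-group contingency table (Yates continuity
    correction off by default, available via ``correction``); summaries are
    n/N (%) of the first level. Missing values are dropped per side.
    """
    ls = pd.Series(left).dropna()
    rs = pd.Series(right).dropna()
    if ls.empty or rs.empty:
        raise InsufficientDataError("both groups must be non-empty")
    if kind == "continuous":
        p = _ranksum_p(ls.to_numpy(float), rs.to_numpy(float))
        try:
            sl, sr = str(summarize_continuous(ls)), str(summarize_continuous(rs))
        except InsufficientDataError as err:
            warnings.warn(f"degenerate summary for {variable!r}: {err}")
            sl, sr = f"n={len(ls)}", f"n={len(rs)}"
        test = "wilcoxon"
    elif kind == "categorical":
        levels = sorted(set(ls) | set(rs))
        table = np.array(
            [[(ls == lv).sum() for lv in levels], [(rs == lv).sum() for lv in levels]]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise UndefinedTestError("contingency table has an all-zero margin")
        if table.shape[1] < 2:
            raise UndefinedTestError("categorical variable has a single level")
        p = float(stats.chi2_contingency(table, correction=correction).pvalue)
        lv = levels[-1]  # report the "positive" (last-sorted) level
        sl = f"{(ls == lv).sum()}/{len(ls)} ({proportion((ls == lv).sum(), len(ls))}%)"
        sr = f"{(rs == lv).sum()}/{len(rs)} ({proportion((rs == lv).sum(), len(rs))}%)"
        test = "chi-square"
    else:
        raise ValueError(f"kind must be continuous or categorical, got {kind!r}")
    return GroupComparison(variable, sl, sr, test, p, p < ALPHA)


def proportion(numerator: int, denominator: int) -> float:
    """Percentage 100*numerator/denominator, exact rational arithmetic,
    rounded half-up to 2 decimals (74/143 -> 51.75)."""
    numerator, denominator = int(numerator), int(denominator)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must be within [0, denominator]")
    return float(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


#: Default Table-1 row layout: (column, kind)
DEFAULT_TABLE1_VARIABLES = [
    ("age", "continuous"),
    ("nihss", "continuous"),
    ("volume_ml", "continuous"),
    ("mrs_binary", "categorical"),
]


def build_table1(
    records: pd.DataFrame,
    variables: list[tuple[str, str]] | None = None,
    correction: bool = False,
) -> pd.DataFrame:
    """Left- vs right-hemisphere comparison table.

    One row per requested variable in the configured order; variables absent
    from the records are listed in a warning and skipped. Degenerate tests
    (e.g. two-patient cohorts) warn rather than crash, reporting p = NaN.
    """
    variables = variables if variables is not None else DEFAULT_TABLE1_VARIABLES
    if "hemisphere" not in records.columns:
        raise ValueError("records must carry a hemisphere column")
    left = records[records["hemisphere"] == "left"]
    right = records[records["hemisphere"] == "right"]
    rows = []
    skipped = []
    for var, kind in variables:
        if var not in records.columns:
            skipped.append(var)
            continue
        try:
            cmp = compare_groups(left[var], right[var], kind, var, correction)
        except (InsufficientDataError, UndefinedTestError, ValueError) as err:
            warnings.warn(f"degenerate comparison for {var!r}: {err}")
            cmp = GroupComparison(
                var, f"n={left[var].notna().sum()}", f"n={right[var].notna().sum()}",
                "wilcoxon" if kind == "continuous" else "chi-square", float("nan"), False,
            )
        rows.append(
            {
                "variable": cmp.variable,
                "left": cmp.summary_left,
                "right": cmp.summary_right,
                "test": cmp.test,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            }
        )
    if skipped:
        warnings.warn(f"variables absent from records, skipped: {skipped}")
    return pd.DataFrame(
        rows, columns=["variable", "left", "right", "test", "p_value", "significant"]
    )
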