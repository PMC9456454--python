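"""Two-group comparisons as reported in small-animal phenotyping studies:
percent change of group means, unpaired Student's t (pooled variance, also
directly from printed means ± SEM), Welch's t, and the Mann-Whitney U test
with an exact small-sample null.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GroupComparison",
    "percent_change",
    "format_percent",
    "student_t_from_summary",
    "welch_t_from_summary",
    "student_t",
    "mann_whitney",
    "summarize",
    "comparison_table",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    units: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise StatsError("group n must be >= 2")
        if self.sem < 0:
            raise StatsError("SEM must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class GroupComparison:
    reference: GroupSummary
    test: GroupSummary
    percent_change: float
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None

    def as_dict(self) -> dict:
        return {
            "reference": self.reference.label,
            "test": self.test.label,
            "ref_mean": self.reference.mean,
            "ref_sem": self.reference.sem,
            "ref_n": self.reference.n,
            "test_mean": self.test.mean,
            "test_sem": self.test.sem,
            "test_n": self.test.n,
            "percent_change": self.percent_change,
            "percent_change_printed": format_percent(self.percent_change),
            "test_name": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def percent_change(reference_mean: float, test_mean: float) -> float:
    """100 * (test - reference) / reference."""
    if reference_mean == 0:
        raise StatsError("reference mean must be nonzero")
    return 100.0 * (test_mean - reference_mean) / reference_mean


def format_percent(value: float) -> str:
    """Printing convention of the result tables: signed, nearest integer
    percent, one decimal when the magnitude is below 10 (half rounds away
    from zero, so +19.5 prints as +20%)."""
    if abs(value) < 10.0:
        v = np.sign(value) * np.floor(abs(value) * 10.0 + 0.5) / 10.0
        return f"{v:+.1f}%"
    v = int(np.sign(value) * np.floor(abs(value) + 0.5))
    return f"{v:+d}%"


def _compare(ref: GroupSummary, test: GroupSummary, name: str, stat: float, p: float, df=None):
    return GroupComparison(
        reference=ref,
        test=test,
        percent_change=percent_change(ref.mean, test.mean),
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        df=df,
    )


def student_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> GroupComparison:
    """Pooled-variance unpaired t-test from printed means ± SEM.

    SDs are reconstructed as sem * sqrt(n); df = n1 + n2 - 2; identical to
    the raw-sample test whenever raw samples match the summaries.
    """
    if g1.sem <= 0 or g2.sem <= 0:
        raise StatsError("summary t-test requires positive SEMs")
    t, p = sps.ttest_ind_from_stats(g2.mean, g2.sd, g2.n, g1.mean, g1.sd, g1.n, equal_var=True)
    return _compare(g1, g2, "student_t", t, p, df=g1.n + g2.n - 2)


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> GroupComparison:
    """Welch's unequal-variance t with Satterthwaite df, from summaries."""
    if g1.sem <= 0 or g2.sem <= 0:
        raise StatsError("summary t-test requires positive SEMs")
    t, p = sps.ttest_ind_from_stats(g2.mean, g2.sd, g2.n, g1.mean, g1.sd, g1.n, equal_var=False)
    v1, v2 = g1.sem**2, g2.sem**2
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return _compare(g1, g2, "welch_t", t, p, df=float(df))


def summarize(label: str, values, units: str = "") -> GroupSummary:
    values = np.asarray(values, float)
    if len(values) < 2:
        raise StatsError("need >= 2 observations")
    return GroupSummary(
        label=label,
        n=len(values),
        mean=float(values.mean()),
        sem=float(values.std(ddof=1) / np.sqrt(len(values))),
        units=units,
    )


def student_t(label1: str, raw1, label2: str, raw2) -> GroupComparison:
    """Pooled-variance t-test on raw samples."""
    g1, g2 = summarize(label1, raw1), summarize(label2, raw2)
    t, p = sps.ttest_ind(np.asarray(raw2, float), np.asarray(raw1, float), equal_var=True)
    return _compare(g1, g2, "student_t", t, p, df=g1.n + g2.n - 2)


def mann_whitney(label1: str, raw1, label2: str, raw2) -> GroupComparison:
    """Mann-Whitney U with exact small-sample null.

    The exact null distribution is used when min(n1, n2) <= 8, n1*n2 <= 100
    and there are no ties; otherwise the normal approximation with tie and
    continuity correction.  Raw observations are required — printed
    summaries carry no rank information.
    """
    x1, x2 = np.asarray(raw1, float), np.asarray(raw2, float)
    if len(x1) < 3 or len(x2) < 3:
        raise StatsError("mann_whitney requires >= 3 raw observations per group")
    ties = len(np.unique(np.concatenate([x1, x2]))) < len(x1) + len(x2)
    exact = min(len(x1), len(x2)) <= 8 and len(x1) * len(x2) <= 100 and not ties
    res = sps.mannwhitneyu(x2, x1, alternative="two-sided", method="exact" if exact else "asymptotic")
    g1, g2 = summarize(label1, x1), summarize(label2, x2)
    return _compare(g1, g2, "mann_whitney_exact" if exact else "mann_whitney_normal",
                    res.statistic, res.pvalue)


def comparison_table(
    df: pd.DataFrame,
    group_col: str,
    reference: str,
    test: str,
    params: list[str] | None = None,
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """One comparison row per parameter column.

    ``method='auto'`` applies a Shapiro-Wilk pre-screen (only when both
    groups have n >= 5) and switches to Mann-Whitney when either group
    fails it; otherwise Student's t.  The test actually used is recorded in
    every row.  Parameters missing in one group are skipped with a warning
    column rather than raised.
    """
    if params is None:
        params = [c for c in df.columns if c != group_col and np.issubdtype(df[c].dtype, np.number)]
    ref_df = df[df[group_col] == reference]
    test_df = df[df[group_col] == test]
    if len(ref_df) < 2 or len(test_df) < 2:
        raise StatsError("need >= 2 specimens per group")
    rows = []
    for p in params:
        x1 = ref_df[p].dropna().to_numpy(float)
        x2 = test_df[p].dropna().to_numpy(float)
        if len(x1) < 2 or len(x2) < 2:
            continue
        use = method
        screen = ""
        if method == "auto":
            use = "student_t"
            if len(x1) >= 5 and len(x2) >= 5:
                w1 = sps.shapiro(x1).pvalue
                w2 = sps.shapiro(x2).pvalue
                screen = f"shapiro p=({w1:.3f},{w2:.3f})"
                if min(w1, w2) < normality_alpha and min(len(x1), len(x2)) >= 3:
                    use = "mann_whitney"
        if use == "student_t":
            cmp = student_t(reference, x1, test, x2)
        elif use == "mann_whitney":
            cmp = mann_whitney(reference, x1, test, x2)
        else:
            raise StatsError(f"unknown method {use!r}")
        row = {"parameter": p, **cmp.as_dict(), "normality_screen": screen}
        rows.append(row)
    return pd.DataFrame(rows)
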