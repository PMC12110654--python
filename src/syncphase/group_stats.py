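"""Between-group statistics: pooled t-tests, Cohen's d, Mann-Whitney U,
Pearson correlations, and leave-one-dyad-out sensitivity.

The primary comparison is Student's pooled-variance two-sample t-test
with Cohen's d standardized by the pooled SD.  With equal group sizes n,
t = d * sqrt(n/2), so printed group means/SDs fully determine both
statistics; ``t_and_d`` therefore accepts either raw samples or
(mean, sd, n) summaries.  Welch's test is available behind a flag.
No multiple-testing correction is applied by default; a Holm option
exists for users who want family-wise control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateSignalError, ValidationError

__all__ = [
    "Summary",
    "GroupComparison",
    "CorrelationResult",
    "t_and_d",
    "mann_whitney",
    "pearson",
    "leave_one_out",
    "aq_summary",
    "compare_groups",
    "holm_correction",
]


@dataclass(frozen=True)
class Summary:
    """Printed-style group summary: mean, sample SD, and n."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """Two-group statistical result (t or U, df, p, effect size)."""

    metric_name: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float | None
    df: float | None
    p_two_sided: float
    cohens_d: float | None
    test: str = "student_t"
    u_stat: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with two-sided p."""

    x_name: str
    y_name: str
    r: float
    p_two_sided: float
    n: int


def _as_summary(sample) -> Summary:
    if isinstance(sample, Summary):
        return sample
    if isinstance(sample, tuple) and len(sample) == 3:
        return Summary(float(sample[0]), float(sample[1]), int(sample[2]))
    arr = np.asarray(sample, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise ValidationError("each group needs at least 2 observations")
    return Summary(float(np.mean(arr)), float(np.std(arr, ddof=1)), len(arr))


def t_and_d(
    group_a,
    group_b,
    *,
    metric_name: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-sample t-test and Cohen's d from samples or summaries.

    Parameters
    ----------
    group_a, group_b
        Raw samples (array-like) or summaries (``Summary`` or a
        ``(mean, sd, n)`` tuple).  NaNs in raw samples are dropped.
    welch
        Use Welch's unequal-variance t and Welch-Satterthwaite df
        instead of the pooled test.  Cohen's d stays pooled-SD.

    Notes
    -----
    The pooled test has df = n_a + n_b - 2 and
    d = (mean_a - mean_b) / s_pooled with
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    p is two-sided.

    Raises
    ------
    DegenerateSignalError
        Zero pooled variance.
    """
    a, b = _as_summary(group_a), _as_summary(group_b)
    if a.n < 2 or b.n < 2:
        raise ValidationError("each group needs n >= 2")
    va, vb = a.sd**2, b.sd**2
    pooled_var = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
    if pooled_var == 0.0:
        raise DegenerateSignalError("zero pooled variance")
    s_pooled = math.sqrt(pooled_var)
    d = (a.mean - b.mean) / s_pooled
    if welch:
        se = math.sqrt(va / a.n + vb / b.n)
        t = (a.mean - b.mean) / se
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    else:
        se = s_pooled * math.sqrt(1.0 / a.n + 1.0 / b.n)
        t = (a.mean - b.mean) / se
        df = a.n + b.n - 2
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(
        metric_name=metric_name,
        mean_a=a.mean, sd_a=a.sd, n_a=a.n,
        mean_b=b.mean, sd_b=b.sd, n_b=b.n,
        t_stat=float(t), df=float(df), p_two_sided=p, cohens_d=float(d),
        test="welch_t" if welch else "student_t",
    )


def mann_whitney(
    sample_a,
    sample_b,
    *,
    metric_name: str = "",
    continuity: bool = True,
) -> GroupComparison:
    """Mann-Whitney U test with midrank tie handling.

    Uses exact enumeration when both samples have n <= 8 and no ties are
    present, otherwise the normal approximation with tie correction
    (continuity correction on by default).  The reported U is the
    statistic of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=continuity
    )
    return GroupComparison(
        metric_name=metric_name,
        mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)) if len(a) > 1 else math.nan,
        n_a=len(a),
        mean_b=float(np.mean(b)), sd_b=float(np.std(b, ddof=1)) if len(b) > 1 else math.nan,
        n_b=len(b),
        t_stat=None, df=None,
        p_two_sided=float(res.pvalue), cohens_d=None,
        test="mann_whitney", u_stat=float(res.statistic),
    )


def pearson(x, y, *, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson r with two-sided p from the t transform (df = n - 2).

    Raises
    ------
    ValidationError
        Fewer than 3 paired observations, mismatched lengths, or a
        constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        x_name=x_name, y_name=y_name,
        r=float(res.statistic), p_two_sided=float(res.pvalue), n=len(x),
    )


def aq_summary(aq_values) -> tuple[float, float]:
    """Mean and sample SD of a set of questionnaire scores.

    SD is NaN for a single value.
    """
    v = np.asarray(aq_values, dtype=float)
    if len(v) == 0:
        raise ValidationError("empty score list")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
    return float(np.mean(v)), sd


def _two_groups(df: pd.DataFrame, group_col: str) -> tuple[str, str]:
    levels = list(pd.unique(df[group_col]))
    if len(levels) != 2:
        raise ValidationError(
            f"group column {group_col!r} must have exactly 2 levels, got {levels}"
        )
    return levels[0], levels[1]


def compare_groups(
    df: pd.DataFrame,
    metrics: Sequence[str],
    *,
    group_col: str = "group",
    welch: bool = False,
) -> dict[str, GroupComparison]:
    """Pooled t/d for each metric column, group A = first-appearing level."""
    lvl_a, lvl_b = _two_groups(df, group_col)
    out = {}
    for m in metrics:
        a = df.loc[df[group_col] == lvl_a, m].to_numpy(dtype=float)
        b = df.loc[df[group_col] == lvl_b, m].to_numpy(dtype=float)
        out[m] = t_and_d(a, b, metric_name=m, welch=welch)
    return out


def leave_one_out(
    df: pd.DataFrame,
    metric: str,
    excluded_dyad: str,
    *,
    group_col: str = "group",
    dyad_col: str = "dyad_id",
    welch: bool = False,
) -> GroupComparison:
    """Recompute t/d for one metric with a single dyad excluded.

    Used to check that a group difference is not driven by one extreme
    pair: excluding a dyad from a group of 18 drops df to 33.

    Raises
    ------
    ValidationError
        Unknown dyad id.
    """
    mask = df[dyad_col].astype(str) == str(excluded_dyad)
    if not mask.any():
        raise ValidationError(f"unknown dyad {excluded_dyad!r}")
    return compare_groups(
        df.loc[~mask], [metric], group_col=group_col, welch=welch
    )[metric]


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
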