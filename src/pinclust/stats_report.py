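"""Group comparisons and mean ± SD summary tables.

Wraps the standard two-sample tests used for the cluster statistics —
Mann–Whitney U (exact small-sample null when both groups have at most
8 observations and no ties; mid-rank normal approximation otherwise) and
equal-variance / Welch t-tests — and renders the usual significance stars.
Star thresholds are explicit and configurable rather than hard-coded,
because legend conventions vary; the summary output always carries the raw
p-values.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GroupComparison

#: default star mapping, most significant first: (p threshold, stars)
DEFAULT_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

TESTS = ("mann_whitney", "t_equal_var", "t_welch")
EXACT_MAX_N = 8  # largest per-group n for which the exact MW null is used


def stars_for(p: float, thresholds=DEFAULT_STAR_THRESHOLDS) -> str:
    for cutoff, sym in sorted(thresholds):
        if p < cutoff:
            return sym
    return "ns"


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "mann_whitney",
    label_a: str = "a",
    label_b: str = "b",
    star_thresholds=DEFAULT_STAR_THRESHOLDS,
    mw_method: Optional[str] = None,
) -> GroupComparison:
    """Two-sided comparison of two samples.

    ``mw_method`` overrides the Mann–Whitney null ("exact" or "asymptotic");
    by default the exact null is used when both samples have at most
    8 observations and the pooled data contain no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}")
    min_n = 1 if test == "mann_whitney" else 2
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"{test} needs at least {min_n} observations per group")

    flags: list[str] = []
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = mw_method
        if method is None:
            method = "exact" if (len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N) else "asymptotic"
        if method == "exact" and has_ties:
            method = "asymptotic"
            flags.append("ties: exact null unavailable, used mid-rank approximation")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                statistic, p = 0.0, 1.0
                flags.append("zero variance in both samples with equal means; p = 1 by convention")
            else:
                statistic, p = float(np.inf if a[0] > b[0] else -np.inf), 0.0
                flags.append("zero variance in both samples with unequal means; p = 0 by convention")
            return _comparison(a, b, test, statistic, p, label_a, label_b, star_thresholds, flags)
        res = stats.ttest_ind(a, b, equal_var=(test == "t_equal_var"))
        statistic, p = float(res.statistic), float(res.pvalue)

    return _comparison(a, b, test, statistic, p, label_a, label_b, star_thresholds, flags)


def _comparison(a, b, test, statistic, p, label_a, label_b, star_thresholds, flags) -> GroupComparison:
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
        sd_b=float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
        test=test,
        statistic=statistic,
        p_value=float(p),
        stars=stars_for(p, star_thresholds),
        flags=tuple(flags),
    )


def summarize(
    records: pd.DataFrame,
    control: str,
    group_col: str = "group",
    value_col: str = "value",
    test: str = "mann_whitney",
    star_thresholds=DEFAULT_STAR_THRESHOLDS,
) -> pd.DataFrame:
    """Per-group n / mean / SD plus the comparison row against the control.

    Groups with a single observation report SD 0 with a flag.  The control
    group's comparison columns are empty.
    """
    if control not in set(records[group_col]):
        raise ValueError(f"unknown control label {control!r}")
    control_values = records.loc[records[group_col] == control, value_col].to_numpy(dtype=float)
    rows = []
    for group, sub in records.groupby(group_col, sort=False):
        values = sub[value_col].to_numpy(dtype=float)
        flags = [] if len(values) > 1 else ["single observation; SD reported as 0"]
        row = {
            "group": group,
            "n": len(values),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            "flags": "; ".join(flags),
        }
        if group != control:
            cmp = compare_groups(values, control_values, test=test, label_a=str(group), label_b=control,
                                 star_thresholds=star_thresholds)
            row.update({"test": test, "statistic": cmp.statistic, "p_value": cmp.p_value, "stars": cmp.stars})
        else:
            row.update({"test": "", "statistic": np.nan, "p_value": np.nan, "stars": ""})
        rows.append(row)
    return pd.DataFrame(rows)
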