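"""Cohort-level summaries and the Wilcoxon rank-sum test.

Group sizes here are tiny (4–9 animals), so the two-sample comparison is the
non-parametric rank-sum test with an *exact* null distribution whenever the
combined sample size allows (≤ 20: full enumeration of rank assignments,
midranks for ties).  Larger samples fall back to the normal approximation
with tie correction and continuity correction.  Tests are two-sided; no
multiple-testing correction is applied, but the number of uncorrected
contrasts is reported so the caller can see it.

Summaries are mean ± standard error (SE = s / √n with the n−1 sample
standard deviation) per group and metric, with pairwise p-values rendered in
the asterisk tiers used in the source field's figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError

_EXACT_LIMIT = 20  # combined n at or below which the exact null is enumerated

#: significance tiers, threshold -> label (checked most stringent first)
SIGNIFICANCE_TIERS = (
    (0.00001, "*****"),
    (0.00005, "****"),
    (0.005, "**"),
    (0.05, "*"),
)


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first sample (midranks)
    pvalue: float  # two-sided
    method: str  # "exact" or "normal"


def significance_label(p: float) -> str:
    for threshold, label in SIGNIFICANCE_TIERS:
        if p < threshold:
            return label
    return "ns"


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the sum of midranks of ``a`` in the pooled sample.
    For combined n ≤ 20 the two-sided p is exact: every C(n, n_a) assignment
    of pooled ranks to group a is enumerated and
    ``p = P(|W - E[W]| >= |w_obs - E[W]|)`` under the permutation null.
    Larger samples use the normal approximation with tie and continuity
    corrections.  If every pooled value is identical the test is degenerate
    and returns p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each sample must have at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigurationError("rank-sum test requires finite values")

    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    w_obs = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; rank-sum test degenerate")
        return RankSumResult(w_obs, 1.0, "degenerate")

    if n <= _EXACT_LIMIT:
        dev = abs(w_obs - mu)
        hits = sum(
            1
            for idx in combinations(range(n), n_a)
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9
        )
        return RankSumResult(w_obs, hits / comb(n, n_a), "exact")

    # normal approximation, tie-corrected variance, continuity correction
    n_b = n - n_a
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(z)
    return RankSumResult(w_obs, min(p, 1.0), "normal")


@dataclass
class GroupSummary:
    """Per-group descriptive stats and the pairwise p-value matrix."""

    summary: pd.DataFrame  # group, metric, n, mean, se
    pairwise: pd.DataFrame  # metric, group_a, group_b, statistic, pvalue, significance
    n_uncorrected_contrasts: int


def summarize_groups(table: pd.DataFrame) -> GroupSummary:
    """Mean ± SE per group and all pairwise rank-sum contrasts.

    ``table`` is tidy with columns ``animal_id, group, metric, value`` (one
    row per animal × metric).  Groups with fewer than 2 animals are excluded
    from testing with a warning.  P-values are uncorrected — their count is
    reported so downstream consumers can adjust if they wish.
    """
    required = {"animal_id", "group", "metric", "value"}
    if not required.issubset(table.columns):
        raise ConfigurationError(
            f"cohort table needs columns {sorted(required)}; got {sorted(table.columns)}"
        )
    dup = table.duplicated(subset=["animal_id", "metric"])
    if dup.any():
        raise ConfigurationError("cohort table has duplicate animal_id x metric rows")

    rows = []
    for (group, metric), sub in table.groupby(["group", "metric"], sort=False):
        v = sub["value"].to_numpy(dtype=float)
        se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
        rows.append(
            {"group": group, "metric": metric, "n": v.size, "mean": float(v.mean()), "se": se}
        )
    summary = pd.DataFrame(rows)

    testable = {g for g in table["group"].unique() if (table["group"] == g).sum() >= 1}
    small = [
        g
        for g in table["group"].unique()
        if table[table["group"] == g]["animal_id"].nunique() < 2
    ]
    if small:
        warnings.warn(f"group(s) {small} have n < 2 and are excluded from testing")
        testable -= set(small)

    contrasts = []
    for metric, sub in table.groupby("metric", sort=False):
        groups = [g for g in sub["group"].unique() if g in testable]
        for ga, gb in combinations(groups, 2):
            va = sub[sub["group"] == ga]["value"].to_numpy(dtype=float)
            vb = sub[sub["group"] == gb]["value"].to_numpy(dtype=float)
            res = rank_sum_test(va, vb)
            contrasts.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "statistic": res.statistic,
                    "pvalue": res.pvalue,
                    "method": res.method,
                    "significance": significance_label(res.pvalue),
                }
            )
    pairwise = pd.DataFrame(
        contrasts,
        columns=["metric", "group_a", "group_b", "statistic", "pvalue", "method", "significance"],
    )
    return GroupSummary(summary, pairwise, len(pairwise))
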