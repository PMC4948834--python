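"""Moderate-vs-severe group comparisons.

Group summaries report mean +/- sample standard deviation (n-1
denominator) per group.  The two-sided Wilcoxon rank-sum test is exact
for the cohort sizes used here (4 vs 4): the null distribution of the
rank-sum statistic is enumerated over all C(n1+n2, n1) group
assignments, with midranks for ties.  Genus-level differences between
groups are ranked by the absolute difference of group-mean relative
abundances, expressed in percentage points.
"""

from __future__ import annotations

import warnings
from math import comb, floor

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .profiling import AbundanceTable


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with halves away from zero, matching printed tables."""
    factor = 10.0 ** decimals
    return np.sign(x) * floor(abs(x) * factor + 0.5) / factor


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group n, mean, and n-1 standard deviation of one variable.

    A group of size 1 gets SD 0 and ``sd_degenerate=True``.
    """
    groups = groups.reindex(values.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    rows = {}
    for label, sub in values.groupby(groups):
        if len(sub) == 0:
            raise ValueError(f"group {label!r} is empty")
        degenerate = len(sub) == 1
        rows[label] = {
            "n": len(sub),
            "mean": float(sub.mean()),
            "sd": 0.0 if degenerate else float(sub.std(ddof=1)),
            "sd_degenerate": degenerate,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _exact_ranksum_pvalue(doubled: np.ndarray, n1: int, w2_obs: int) -> float:
    """Exact two-sided p via subset-sum counting over doubled midranks.

    Counts size-``n1`` subsets of the doubled (hence integer) midranks
    whose rank sum deviates from the null mean at least as much as the
    observed sum.  Deviations are compared on the integer scale
    ``|n * W2 - n1 * total2|`` to avoid float ties.
    """
    n = len(doubled)
    total2 = int(doubled.sum())
    # dp[k] maps achievable subset sum -> number of size-k subsets
    dp: list[dict[int, int]] = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in doubled:
        for k in range(min(n1, n) - 1, -1, -1):
            for s, cnt in list(dp[k].items()):
                dp[k + 1][s + int(r)] = dp[k + 1].get(s + int(r), 0) + cnt
    dev_obs = abs(n * w2_obs - n1 * total2)
    extreme = sum(
        cnt for s, cnt in dp[n1].items() if abs(n * s - n1 * total2) >= dev_obs
    )
    return extreme / comb(n, n1)


def wilcoxon_rank_sum_exact(x, y, max_exact: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value, exact for small samples.

    For combined sizes up to ``max_exact`` the p-value is computed from
    the complete permutation distribution of the rank-sum statistic
    (midranks for ties): p = P(|W - E[W]| >= |w_obs - E[W]|).  Larger
    inputs fall back to the normal approximation with a warning.
    Identical samples give p = 1; fully separated 4-vs-4 samples give
    2/70.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n = x.size + y.size
    if n > max_exact:
        warnings.warn(
            f"combined sample size {n} exceeds {max_exact}; "
            "using normal approximation",
            stacklevel=2,
        )
        return float(mannwhitneyu(x, y, method="asymptotic").pvalue)
    ranks = rankdata(np.concatenate([x, y]))
    doubled = np.round(2 * ranks).astype(np.int64)
    w2_obs = int(doubled[: x.size].sum())
    return _exact_ranksum_pvalue(doubled, x.size, w2_obs)


def percent_difference_ranking(
    rel_table: AbundanceTable,
    top_n: int = 10,
    mode: str = "sample_mean",
    group_order: tuple[str, str] | None = None,
    sample_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank taxa by the between-group difference of mean relative abundance.

    Per taxon, the difference is mean(group1) - mean(group2) of
    per-sample proportions (``mode="sample_mean"``, default) or of
    pooled proportions (``mode="pooled"``, weighting each sample's
    proportions by its ``sample_weights`` read total), expressed in
    percentage points.  Taxa are ranked 1..N by
    non-increasing absolute difference, ties broken by lexicographic
    taxon name; the signed difference is retained so direction is
    preserved.  ``top_n`` larger than the taxon count returns all taxa.
    """
    if not rel_table.is_relative:
        raise ValueError("ranking requires a relative abundance table")
    if rel_table.groups is None:
        raise ValueError("table carries no group labels")
    if mode not in ("sample_mean", "pooled"):
        raise ValueError("mode must be 'sample_mean' or 'pooled'")
    labels = sorted(rel_table.groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    if group_order is not None:
        if sorted(group_order) != labels:
            raise ValueError("group_order must name the two group labels")
        labels = list(group_order)
    g1, g2 = labels

    means = {}
    for g in (g1, g2):
        block = rel_table.counts.loc[rel_table.groups == g]
        if mode == "sample_mean" or sample_weights is None:
            means[g] = block.mean(axis=0)
        else:
            w = sample_weights.reindex(block.index).to_numpy(dtype=float)
            means[g] = pd.Series(
                np.average(block.to_numpy(), axis=0, weights=w),
                index=block.columns,
            )

    diff_pp = (means[g1] - means[g2]) * 100.0
    out = pd.DataFrame(
        {
            "genus": diff_pp.index,
            f"mean_{g1}": means[g1].to_numpy(),
            f"mean_{g2}": means[g2].to_numpy(),
            "difference_pp": diff_pp.to_numpy(),
        }
    )
    out["abs_difference"] = out["difference_pp"].abs()
    out = out.sort_values(
        ["abs_difference", "genus"], ascending=[False, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.drop(columns="abs_difference").head(top_n)
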