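"""Unique-read consensus analysis with CV-quartile filtering.

To dampen individual variation in a small cohort, this analysis
restricts attention to "unique reads" — reads mapping to exactly one
reference identifier at or above the similarity threshold (90% for 16S,
95% for metatranscriptome data) — and to genera detected in every
sample of a group.  For each such genus the coefficient of variation
CV = sigma / mu of its per-sample unique-read counts is computed within
each group; genera in the lowest CV quartile are considered stably
detected, and the between-group differences of their mean unique-read
counts are ranked in descending magnitude.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .profiling import AbundanceTable, aggregate_by_rank


def select_unique_reads(
    assignments: pd.DataFrame, similarity_threshold: float
) -> pd.DataFrame:
    """Keep reads with exactly one assignment at or above the threshold.

    A read with several supra-threshold hits is ambiguous and dropped;
    sub-threshold hits do not count, so a read with one hit at 96% and
    another at 94% is retained (threshold 95) via the single 96% hit.
    """
    passing = assignments[assignments["similarity"] >= similarity_threshold]
    hit_counts = passing.groupby("read_id")["read_id"].transform("size")
    return passing[hit_counts == 1]


def unique_read_table(
    assignments: dict[str, pd.DataFrame],
    similarity_threshold: float,
    groups: pd.Series | None = None,
    rank: str = "genus",
) -> AbundanceTable:
    """Per-sample unique-read counts aggregated at ``rank``."""
    selected = {
        s: select_unique_reads(df, similarity_threshold)
        for s, df in assignments.items()
    }
    return aggregate_by_rank(selected, rank, groups=groups)


def group_common_genera(table: AbundanceTable) -> dict[str, list[str]]:
    """Genera detected (count > 0) in every sample of each group."""
    if table.groups is None:
        raise ValueError("table carries no group labels")
    out = {}
    for label in sorted(table.groups.dropna().unique()):
        block = table.counts.loc[table.groups == label]
        present_everywhere = (block > 0).all(axis=0)
        out[label] = sorted(block.columns[present_everywhere])
    return out


def consensus_records(table: AbundanceTable) -> pd.DataFrame:
    """Per-group, per-genus unique-read statistics for group-common genera.

    Columns: ``group, genus, mean, sd, cv`` with mean over the group's
    samples, SD with the n-1 denominator, and CV = sd / mean.  Only
    genera detectable in every sample of the group appear (so mean > 0
    always holds here); a genus whose counts are constant has CV 0.
    """
    common = group_common_genera(table)
    rows = []
    for label, genera in common.items():
        block = table.counts.loc[table.groups == label]
        for genus in genera:
            vals = block[genus].to_numpy(dtype=float)
            mu = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {"group": label, "genus": genus, "mean": mu, "sd": sd, "cv": sd / mu}
            )
    return pd.DataFrame(rows, columns=["group", "genus", "mean", "sd", "cv"])


def _assign_quartile_bins(cvs: np.ndarray) -> np.ndarray:
    """Quartile bin (1-4) per CV by ascending rank; ties take the lower bin."""
    n = len(cvs)
    order = np.argsort(cvs, kind="stable")
    pos_bin = 4 * np.arange(n) // n + 1  # bin of each sorted position
    bins = np.empty(n, dtype=int)
    bins[order] = pos_bin
    # ties share the minimum bin among their positions
    out = bins.copy()
    for value in np.unique(cvs):
        mask = cvs == value
        out[mask] = bins[mask].min()
    return out


def cv_quartile_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Retain the lowest-CV quartile of genera, per group.

    CVs are binned into four quartiles by ascending value within each
    group; records in the first quartile are flagged ``retained``.
    Groups with fewer than 4 genera keep everything (with a warning);
    a genus with zero mean is excluded before binning and flagged
    ``zero_mean``.
    """
    out = records.copy()
    out["zero_mean"] = out["mean"] == 0
    out["quartile_bin"] = 0
    out["retained"] = False
    for label, idx in out.groupby("group").groups.items():
        sub = out.loc[idx]
        eligible = sub.index[~sub["zero_mean"]]
        if len(eligible) < 4:
            warnings.warn(
                f"group {label!r} has fewer than 4 eligible genera; "
                "all retained",
                stacklevel=2,
            )
            out.loc[eligible, "quartile_bin"] = 1
            out.loc[eligible, "retained"] = True
            continue
        bins = _assign_quartile_bins(out.loc[eligible, "cv"].to_numpy())
        out.loc[eligible, "quartile_bin"] = bins
        out.loc[eligible, "retained"] = bins == 1
    return out


def rank_unique_differences(
    filtered_records: pd.DataFrame,
    table: AbundanceTable,
    top_n: int = 10,
    mode: str = "union",
) -> pd.DataFrame:
    """Rank retained genera by the between-group difference in mean counts.

    The retained genus sets of the two groups are combined by ``mode``
    ("union": retained in either group; "intersection": in both).  Per
    genus, the difference of group means of per-sample unique-read
    counts is ranked by descending magnitude, ties broken by genus
    name; the signed value is kept.  An empty combined set yields an
    empty ranking with a warning.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    if table.groups is None:
        raise ValueError("table carries no group labels")
    labels = sorted(table.groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    g1, g2 = labels

    retained = {
        g: set(filtered_records.loc[
            (filtered_records["group"] == g) & filtered_records["retained"], "genus"
        ])
        for g in labels
    }
    genera = (
        retained[g1] | retained[g2] if mode == "union" else retained[g1] & retained[g2]
    )
    if not genera:
        warnings.warn("no genera retained in the requested mode", stacklevel=2)
        return pd.DataFrame(
            columns=["rank", "genus", f"mean_{g1}", f"mean_{g2}", "difference"]
        )

    rows = []
    for genus in sorted(genera):
        m1 = float(table.counts.loc[table.groups == g1, genus].mean())
        m2 = float(table.counts.loc[table.groups == g2, genus].mean())
        rows.append(
            {"genus": genus, f"mean_{g1}": m1, f"mean_{g2}": m2, "difference": m1 - m2}
        )
    out = pd.DataFrame(rows)
    out["abs_difference"] = out["difference"].abs()
    out = out.sort_values(
        ["abs_difference", "genus"], ascending=[False, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.drop(columns="abs_difference").head(top_n)


def consensus_analysis(
    assignments: dict[str, pd.DataFrame],
    groups: pd.Series,
    similarity_threshold: float,
    top_n: int = 10,
    mode: str = "union",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full unique-read pipeline: select, tally, CV-filter, rank.

    Returns the per-group consensus records (with quartile bins and
    retention flags) and the ranked between-group difference table.
    """
    table = unique_read_table(assignments, similarity_threshold, groups=groups)
    records = cv_quartile_filter(consensus_records(table))
    ranking = rank_unique_differences(records, table, top_n=top_n, mode=mode)
    return records, ranking
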