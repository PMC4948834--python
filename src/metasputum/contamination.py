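"""Negative-control contamination correction.

A no-template control library sequenced alongside the patient samples
estimates the reagent/background community.  Each taxon's patient
relative abundance p is down-weighted by its control relative abundance
c: corrected = p * (1 - c).  A taxon at 20% in a patient and 2% in the
control becomes 20 * (1 - 0.02) = 19.6%.  Other taxa are not rescaled,
so corrected rows sum to slightly less than 1 (renormalization is
available but off by default).
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .profiling import AbundanceTable


def correct_abundance(p_sample: float, c_control: float) -> float:
    """Corrected relative abundance ``p_sample * (1 - c_control)``.

    Both arguments are fractions in [0, 1]; the result never exceeds
    ``p_sample`` and equals it only when either argument is zero.
    """
    if not 0 <= p_sample <= 1:
        raise ValueError(f"patient abundance must be in [0, 1], got {p_sample}")
    if not 0 <= c_control <= 1:
        raise ValueError(f"control abundance must be in [0, 1], got {c_control}")
    return p_sample * (1.0 - c_control)


def read_control_profile(path) -> pd.Series:
    """Load a ``taxon<TAB>fraction`` control profile."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str})
    return pd.Series(df["fraction"].to_numpy(), index=df["taxon"], name="fraction")


def correct_table(
    table: AbundanceTable,
    control_profile: pd.Series,
    control_rank: str | None = None,
    renormalize: bool = False,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Apply the (1 - c) correction cell-wise to a relative abundance table.

    Taxa absent from the control profile get c = 0 (identity).  Returns
    the corrected table (flagged ``corrected=True`` so the correction
    cannot be applied twice) and a long-format record frame with one row
    per sample x taxon: ``sample, taxon, p_sample, c_control,
    corrected``.
    """
    if not table.is_relative:
        raise ValueError("correction applies to relative abundance tables")
    if table.corrected:
        raise ValueError("table is already corrected; correction is applied once")
    if control_rank is not None and control_rank != table.rank:
        raise ValueError(
            f"control profile rank {control_rank!r} does not match table rank {table.rank!r}"
        )
    if (control_profile < 0).any() or (control_profile > 1).any():
        raise ValueError("control fractions must be in [0, 1]")
    if control_profile.sum() > 1 + 1e-9:
        raise ValueError("control fractions must sum to at most 1")

    c = control_profile.reindex(table.counts.columns).fillna(0.0)
    corrected = table.counts.mul(1.0 - c, axis=1)
    if renormalize:
        totals = corrected.sum(axis=1)
        corrected = corrected.div(totals.where(totals > 0, 1.0), axis=0)

    records = (
        table.counts.stack()
        .rename("p_sample")
        .reset_index()
        .rename(columns={"sample": "sample", "level_1": "taxon"})
    )
    records.columns = ["sample", "taxon", "p_sample"]
    records["c_control"] = c.reindex(records["taxon"]).to_numpy()
    records["corrected"] = records["p_sample"] * (1.0 - records["c_control"])

    out = replace(table, counts=corrected, corrected=True)
    return out, records


def correct_counts(counts: pd.DataFrame, control_profile: pd.Series) -> pd.DataFrame:
    """Count-level analogue: ``round(count * (1 - c))`` per taxon.

    The published per-sample "corrected reads" integers follow no
    stated count-level rule, so this is a convenience transform only;
    downstream statistics use the relative-abundance correction.
    """
    c = control_profile.reindex(counts.columns).fillna(0.0)
    return counts.mul(1.0 - c, axis=1).round().astype(int)
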