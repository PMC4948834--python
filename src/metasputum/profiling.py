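"""Rank-level abundance tables from read-to-taxon assignment tables.

Assignments map a read to a reference sequence with a percent similarity
and a seven-rank lineage (kingdom ... species).  Profiling applies the
similarity threshold (90% for 16S-style alignments, 95% for
metatranscriptome alignments), keeps one best hit per read, aggregates
counts at a chosen rank, and partitions metatranscriptome reads by
kingdom (human / bacteria / archaea / virus / fungi / others).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
ASSIGNMENT_COLUMNS = ("read_id", "ref_id", "similarity", *RANKS)
UNCLASSIFIED = "unclassified"

#: Similarity thresholds mirroring the two experiment types.
SIMILARITY_16S = 90.0
SIMILARITY_RNA = 95.0


def read_assignments(path) -> pd.DataFrame:
    """Load a TSV assignment table (columns ``read_id ref_id similarity`` + ranks)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref_id": str})
    missing = set(ASSIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assignment table missing columns: {sorted(missing)}")
    return df


def filter_by_similarity(assignments: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain assignments with similarity at or above ``threshold`` (inclusive)."""
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be a percentage in [0, 100]")
    return assignments[assignments["similarity"] >= threshold]


def best_hit_per_read(assignments: pd.DataFrame) -> pd.DataFrame:
    """Keep the single best-similarity assignment per read.

    Ties on similarity are broken by lexicographic reference id so that
    the result is deterministic.
    """
    ordered = assignments.sort_values(
        ["read_id", "similarity", "ref_id"], ascending=[True, False, True]
    )
    return ordered.drop_duplicates("read_id")


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix at one taxonomic rank.

    ``counts`` has samples as rows and taxa as columns; ``groups`` maps
    each sample to its cohort label.  ``is_relative`` marks proportion
    tables (rows sum to 1, or 0 for an empty sample); ``corrected``
    marks tables already adjusted against the negative control, which
    guards against applying the correction twice.
    """

    counts: pd.DataFrame
    rank: str
    groups: pd.Series | None = None
    is_relative: bool = False
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.rank not in RANKS and self.rank != "otu":
            raise ValueError(f"unknown rank: {self.rank!r}")
        if (self.counts.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.counts.index)
        if self.is_relative:
            sums = self.counts.sum(axis=1).to_numpy()
            ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0)
            if not (ok | self.corrected).all():
                raise ValueError("relative table rows must sum to 1 (or 0)")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            flags = f"rank={self.rank} relative={self.is_relative} corrected={self.corrected}"
            fh.write(f"# {flags}\n")
            self.counts.to_csv(fh, sep="\t", index_label="sample")


def aggregate_by_rank(
    assignments: dict[str, pd.DataFrame],
    rank: str,
    groups: pd.Series | None = None,
) -> AbundanceTable:
    """Tally per-sample assignment counts at ``rank``.

    ``assignments`` maps sample id to its (already filtered and
    deduplicated) assignment frame.  Assignments with an empty or
    missing value at the rank pool into an ``unclassified`` column.
    Per sample, the row total equals the number of assignments.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    rows = {}
    for sample, df in assignments.items():
        labels = df[rank].fillna("").astype(str).str.strip()
        labels = labels.where(labels != "", UNCLASSIFIED)
        rows[sample] = labels.value_counts()
    counts = pd.DataFrame(rows).T.fillna(0).astype(int)
    counts = counts.reindex(sorted(counts.columns), axis=1)
    counts.index.name = "sample"
    return AbundanceTable(counts, rank=rank, groups=groups)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its total; empty rows stay zero."""
    totals = table.counts.sum(axis=1)
    rel = table.counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return replace(table, counts=rel, is_relative=True)


def filter_otus(otu_counts: pd.DataFrame, min_size: int = 10) -> pd.DataFrame:
    """Drop OTUs (columns) with a total count below ``min_size``.

    An OTU with exactly ``min_size`` reads is retained; surviving OTUs
    keep their per-sample counts unchanged.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    keep = otu_counts.sum(axis=0) >= min_size
    return otu_counts.loc[:, keep]


KINGDOM_CATEGORIES = ("human", "bacteria", "archaea", "virus", "fungi", "others")

_KINGDOM_ALIASES = {
    "bacteria": "bacteria",
    "archaea": "archaea",
    "archaebacteria": "archaea",
    "virus": "virus",
    "viruses": "virus",
    "fungi": "fungi",
}


def kingdom_partition(
    kingdom_counts: pd.DataFrame,
    human_label: str = "Homo sapiens",
    mapped_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sample read fractions over human/bacteria/archaea/virus/fungi/others.

    ``kingdom_counts`` is a samples x kingdom count table of mapped,
    similarity-filtered reads.  Fractions are computed over each
    sample's mapped total — the row sum by default, or an explicit
    ``mapped_totals`` series when the mapped accounting is carried
    separately — and sum to 1 (row-sum case); a sample with zero mapped
    reads gets all-zero fractions and ``zero_mapped=True``.
    """
    cats = {c: np.zeros(len(kingdom_counts)) for c in KINGDOM_CATEGORIES}
    for col in kingdom_counts.columns:
        name = str(col).strip()
        if name == human_label or name.lower() in ("human", human_label.lower()):
            cat = "human"
        else:
            cat = _KINGDOM_ALIASES.get(name.lower(), "others")
        cats[cat] = cats[cat] + kingdom_counts[col].to_numpy(dtype=float)
    out = pd.DataFrame(cats, index=kingdom_counts.index)
    if mapped_totals is not None:
        totals = mapped_totals.reindex(kingdom_counts.index).astype(float)
    else:
        totals = out.sum(axis=1)
    fractions = out.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    fractions["zero_mapped"] = totals == 0
    return fractions
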