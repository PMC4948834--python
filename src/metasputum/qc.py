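"""Demultiplexing and read quality filtering for barcoded FASTQ data.

Reads carry a sample barcode at the 5' end; demultiplexing assigns each
read to the sample whose barcode is nearest in Hamming distance (at most
``max_barcode_mismatch`` mismatches, unique minimum required) and trims
the barcode.  Quality filtering then retains reads that (1) meet the
Phred quality criterion, (2) are at least ``min_length`` bp long after
barcode removal, and (3) contain no ambiguous bases.

Phred scores relate to the base-calling error probability via
Q = -10 log10(P), so Q20 corresponds to a 1% error probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNASSIGNED = "unassigned"
_UNAMBIGUOUS = frozenset("ACGT")


def phred_error_prob(q: float) -> float:
    """Error probability for a Phred quality score: ``10 ** (-q / 10)``.

    ``phred_error_prob(20) == 0.01``; ``phred_error_prob(0) == 1.0``.
    """
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


@dataclass(frozen=True)
class QcPolicy:
    """Quality-filtering thresholds.

    min_quality
        Phred threshold; a read passes if its mean quality (default
        mode) or its minimum per-base quality is at least this value.
    min_length
        Minimum read length in bp, evaluated after barcode trimming.
    max_barcode_mismatch
        Maximum Hamming distance between the 5' prefix and the assigned
        barcode.
    quality_mode
        "mean" or "per-base-min".
    """

    min_quality: int = 20
    min_length: int = 70
    max_barcode_mismatch: int = 2
    quality_mode: str = "mean"

    def __post_init__(self) -> None:
        if not 0 <= self.min_quality <= 41:
            raise ValueError("min_quality must be in [0, 41]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_barcode_mismatch < 0:
            raise ValueError("max_barcode_mismatch must be >= 0")
        if self.quality_mode not in ("mean", "per-base-min"):
            raise ValueError("quality_mode must be 'mean' or 'per-base-min'")


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    qualities: list[int] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads to a Phred+33 FASTQ file; returns the record count."""
    records = (
        SeqRecord(
            Seq(r.bases),
            id=r.id,
            description="",
            letter_annotations={"phred_quality": list(r.qualities)},
        )
        for r in reads
    )
    return SeqIO.write(records, str(path), "fastq")


def read_barcode_map(path) -> dict[str, str]:
    """Load a ``sample_id<TAB>barcode`` table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["barcode"]))


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N matches nothing."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def demultiplex(
    reads: Iterable[Read],
    barcode_map: Mapping[str, str],
    policy: QcPolicy | None = None,
) -> dict[str, list[Read]]:
    """Assign reads to samples by their 5' barcode and trim it.

    A read goes to the sample whose barcode has the minimal Hamming
    distance to the read's prefix, provided that distance is at most
    ``policy.max_barcode_mismatch`` and the minimum is unique; ties and
    too-distant prefixes go to the ``"unassigned"`` bin untrimmed.
    Comparison is case-insensitive and an N in the barcode region counts
    as a mismatch.  Every input read appears in exactly one output bin.
    """
    policy = policy or QcPolicy()
    barcodes = {s: b.upper() for s, b in barcode_map.items()}
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("duplicate barcodes in barcode map")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must have the same length")
    (bc_len,) = lengths

    out: dict[str, list[Read]] = {s: [] for s in barcodes}
    out[UNASSIGNED] = []
    for read in reads:
        if len(read) < bc_len:
            out[UNASSIGNED].append(read)
            continue
        prefix = read.bases[:bc_len].upper()
        dists = {s: hamming(prefix, b) for s, b in barcodes.items()}
        best = min(dists.values())
        hits = [s for s, d in dists.items() if d == best]
        if best <= policy.max_barcode_mismatch and len(hits) == 1:
            out[hits[0]].append(
                Read(read.id, read.bases[bc_len:], list(read.qualities[bc_len:]))
            )
        else:
            out[UNASSIGNED].append(read)
    return out


def passes_quality(read: Read, policy: QcPolicy) -> bool:
    if len(read) < policy.min_length:
        return False
    if any(b not in _UNAMBIGUOUS for b in read.bases.upper()):
        return False
    if policy.quality_mode == "mean":
        return float(np.mean(read.qualities)) >= policy.min_quality
    return min(read.qualities) >= policy.min_quality


def quality_filter(
    reads: Iterable[Read], policy: QcPolicy | None = None
) -> list[Read]:
    """Retain reads passing quality, length and ambiguity rules, in order."""
    policy = policy or QcPolicy()
    return [r for r in reads if passes_quality(r, policy)]


def summarize_qc(counts: pd.DataFrame, total_label: str = "Total") -> pd.DataFrame:
    """Append a column-sum total row to a per-sample read-count table.

    Counts must be non-negative; if ``raw_reads`` and
    ``high_quality_reads`` columns are both present, high-quality counts
    may not exceed raw counts.
    """
    if (counts < 0).any().any():
        raise ValueError("read counts must be non-negative")
    if {"raw_reads", "high_quality_reads"} <= set(counts.columns):
        if (counts["high_quality_reads"] > counts["raw_reads"]).any():
            raise ValueError("high-quality count exceeds raw count")
    summary = counts.copy()
    summary.loc[total_label] = counts.sum(axis=0)
    return summary


def run_qc(
    fastq_path,
    barcode_map: Mapping[str, str],
    policy: QcPolicy | None = None,
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Demultiplex a multiplexed FASTQ and quality-filter each sample.

    Returns per-sample retained reads and a summary frame with raw
    (demultiplexed) and high-quality read counts per sample plus totals.
    """
    policy = policy or QcPolicy()
    binned = demultiplex(read_fastq(fastq_path), barcode_map, policy)
    retained: dict[str, list[Read]] = {}
    rows = {}
    for sample, reads in binned.items():
        if sample == UNASSIGNED:
            continue
        kept = quality_filter(reads, policy)
        retained[sample] = kept
        rows[sample] = {"raw_reads": len(reads), "high_quality_reads": len(kept)}
    summary = summarize_qc(pd.DataFrame.from_dict(rows, orient="index"))
    return retained, summary
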