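"""Shannon diversity, OTU richness summaries, and rarefaction curves.

Shannon diversity H = -sum p_i log p_i is computed on taxon proportion
vectors (natural log by default; the log base is configurable).  The
corrected variant renormalizes negative-control-corrected abundances
internally, since entropy requires a probability vector.  Rarefaction
subsamples reads without replacement at increasing depths and reports
mean genus richness per depth; the hypergeometric closed form for the
expected richness is provided alongside the simulation.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy.stats import entropy


def shannon(counts, base: float | None = None) -> float:
    """Shannon index of a non-negative abundance vector.

    Zero entries are ignored; ``base=None`` means natural log.  A
    single-taxon vector gives 0 and k equal counts give log(k).
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() <= 0:
        raise ValueError("Shannon index requires at least one positive count")
    return float(entropy(arr, base=base))


def shannon_per_sample(counts: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Per-sample Shannon index over the columns of a samples x taxa table."""
    return counts.apply(lambda row: shannon(row.to_numpy(), base=base), axis=1)


def corrected_shannon(corrected_abundances, base: float | None = None) -> float:
    """Shannon index of a corrected (hence unnormalized) abundance vector.

    The vector is renormalized to a probability vector first; entropy of
    an unnormalized measure is undefined.
    """
    return shannon(corrected_abundances, base=base)


def group_mean_otus(otu_counts: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Arithmetic mean OTU richness per group, exact and rounded.

    ``otu_counts`` holds per-sample OTU counts; ``groups`` the cohort
    label per sample.
    """
    groups = groups.reindex(otu_counts.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    out = otu_counts.groupby(groups).agg(mean="mean", n="size")
    if (out["n"] == 0).any():
        raise ValueError("empty group")
    out["mean_rounded"] = np.floor(out["mean"] + 0.5).astype(int)
    return out


def expected_rarefied_richness(counts, depth: int) -> float:
    """Expected number of taxa seen in a depth-read subsample (no replacement).

    Closed form: sum over taxa of 1 - C(N - n_g, d) / C(N, d), with N
    the total reads and n_g the taxon's reads.  Exact integer
    combinatorics, so usable as an oracle for the simulation.
    """
    n = [int(x) for x in np.asarray(counts).ravel() if x > 0]
    total = sum(n)
    if not 0 <= depth <= total:
        raise ValueError("depth must be between 0 and the total count")
    denom = comb(total, depth)
    return float(sum(1.0 - comb(total - ng, depth) / denom for ng in n))


def rarefy(
    counts,
    depth: int,
    replicates: int = 100,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Mean taxon richness over uniform subsamples of ``depth`` reads.

    Subsampling is without replacement (multivariate hypergeometric).
    ``depth`` equal to the total returns the observed richness exactly;
    depth 1 always observes exactly one taxon.
    """
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total reads {total}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    richness = [
        int(np.count_nonzero(rng.multivariate_hypergeometric(arr, depth)))
        for _ in range(replicates)
    ]
    return float(np.mean(richness))


def rarefaction_curve(
    genus_counts,
    depths=None,
    n_depths: int = 10,
    replicates: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean genus richness at increasing subsampling depths.

    ``genus_counts`` are read counts per genus within one phylum.  By
    default 10 evenly spaced depths up to the phylum total are used.
    Returns a frame with ``depth`` and ``mean_richness`` columns; mean
    richness is non-decreasing in depth in expectation and equals the
    observed genus count at full depth.
    """
    arr = np.asarray(genus_counts, dtype=np.int64)
    total = int(arr.sum())
    if total == 0:
        raise ValueError("phylum has no reads")
    if depths is None:
        depths = np.unique(np.linspace(1, total, n_depths).round().astype(int))
    rng = np.random.default_rng(seed)
    rows = [
        {"depth": int(d), "mean_richness": rarefy(arr, int(d), replicates, rng)}
        for d in depths
    ]
    return pd.DataFrame(rows)


def phylum_rarefaction_curves(
    genus_table: pd.DataFrame,
    genus_to_phylum: dict[str, str],
    depths=None,
    replicates: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rarefaction curves per phylum from pooled genus-level read counts.

    ``genus_table`` is a samples x genus count table; counts pool over
    samples within each phylum.  Output columns: ``phylum, depth,
    mean_richness``.
    """
    pooled = genus_table.sum(axis=0)
    frames = []
    for phylum in sorted(set(genus_to_phylum.values())):
        genera = [g for g in pooled.index if genus_to_phylum.get(g) == phylum]
        counts = pooled[genera].to_numpy()
        if counts.sum() == 0:
            continue
        curve = rarefaction_curve(
            counts, depths=depths, replicates=replicates, seed=seed
        )
        curve.insert(0, "phylum", phylum)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True)


def plot_rarefaction(curves: pd.DataFrame, path) -> None:
    """Plot per-phylum rarefaction curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for phylum, sub in curves.groupby("phylum"):
        ax.plot(sub["depth"], sub["mean_richness"], marker="o", label=str(phylum))
    ax.set_xlabel("subsampled reads")
    ax.set_ylabel("mean genus richness")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def diversity_summary(
    counts: pd.DataFrame,
    corrected_counts: pd.DataFrame | None = None,
    otu_counts: pd.Series | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Per-sample Shannon (raw and, if given, corrected) and OTU richness."""
    out = pd.DataFrame({"shannon": shannon_per_sample(counts, base=base)})
    if corrected_counts is not None:
        out["corrected_shannon"] = shannon_per_sample(corrected_counts, base=base)
    if otu_counts is not None:
        out["otus"] = otu_counts.reindex(out.index)
    return out
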