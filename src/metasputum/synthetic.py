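"""Synthetic sputum-microbiome cohorts with known ground truth.

Generates barcoded FASTQ reads, read-to-taxon assignment tables, and
sample metadata with the statistical structure the downstream analysis
assumes: two patient groups (moderate / severe, four samples each by
default) drawn from a shared community in which a few genera carry a
planted multiplicative group effect, plus a no-template negative
control dominated by a reagent-contaminant profile.

Counts follow a Dirichlet-multinomial model: per sample the community
proportions are perturbed by a Dirichlet draw whose concentration is
controlled by a single ``overdispersion`` parameter (0 degenerates to a
plain multinomial).  A configurable fraction of emitted reads is
corrupted — too short, containing N bases, low quality, or assigned
below the similarity floor — to exercise every downstream filter.

Everything is seeded: regenerating with the same seed yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiling import RANKS

MODERATE = "moderate"
SEVERE = "severe"
CONTROL = "control"
GROUPS = (MODERATE, SEVERE, CONTROL)

#: Modes of read corruption; each maps to one downstream filter.
CORRUPTION_MODES = ("short", "ambiguous", "low_quality", "low_similarity")

# Community lineage pool: common sputum/airway genera.
_COMMUNITY_POOL: list[tuple[str, ...]] = [
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", "Streptococcus pneumoniae"),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella", "Veillonella parvula"),
    ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus", "Staphylococcus aureus"),
    ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus", "Bacillus subtilis"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", "Prevotella melaninogenica"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Porphyromonas", "Porphyromonas gingivalis"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", "Bacteroides fragilis"),
    ("Bacteria", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Chryseobacterium", "Chryseobacterium gleum"),
    ("Bacteria", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Capnocytophaga", "Capnocytophaga ochracea"),
    ("Bacteria", "Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium", "Fusobacterium nucleatum"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria", "Neisseria meningitidis"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus", "Haemophilus influenzae"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", "Pseudomonas aeruginosa"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter", "Acinetobacter baumannii"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", "Escherichia coli"),
    ("Bacteria", "Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Campylobacteraceae", "Campylobacter", "Campylobacter concisus"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Rothia", "Rothia mucilaginosa"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Actinomycetales", "Actinomycetaceae", "Actinomyces", "Actinomyces oris"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Mycobacteriales", "Corynebacteriaceae", "Corynebacterium", "Corynebacterium striatum"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Propionibacteriales", "Propionibacteriaceae", "Propionibacterium", "Propionibacterium acnes"),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Blautia", "Blautia obeum"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", "Lactobacillus salivarius"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Lautropia", "Lautropia mirabilis"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Alloprevotella", "Alloprevotella tannerae"),
]

# Reagent-contaminant pool: genera typically dominating no-template controls.
_CONTAMINANT_POOL: list[tuple[str, ...]] = [
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Oceanospirillales", "Halomonadaceae", "Halomonas", "Halomonas titanicae"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Alteromonadales", "Shewanellaceae", "Shewanella", "Shewanella algae"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Ralstonia", "Ralstonia pickettii"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Hyphomicrobiales", "Bradyrhizobiaceae", "Bradyrhizobium", "Bradyrhizobium japonicum"),
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas", "Sphingomonas paucimobilis"),
]

#: Lineage bucket for host reads in metatranscriptome-like designs.
HUMAN_LINEAGE = ("Homo sapiens", "Chordata", "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens")


class DesignError(ValueError):
    """Invalid community design parameters."""


@dataclass
class CommunityDesign:
    """Ground-truth community for a two-group cohort plus negative control.

    taxa
        Seven-rank lineages, contaminants included.
    base_proportions
        Expected proportions in the moderate group (sum to 1).
    group_effects
        Per-taxon multiplicative fold-change applied to the severe
        group (then renormalized); 1 everywhere means no group effect.
    contaminant_indices / control_proportions
        Which taxa constitute the reagent-contaminant profile and their
        expected proportions in the negative control (sum to 1).
    overdispersion
        Dirichlet-multinomial overdispersion; 0 gives a multinomial.
    similarity_floor
        Lower bound of simulated percent similarity for clean reads (90
        emulates 16S-style alignment, 95 metatranscriptome-style).
    """

    taxa: list[tuple[str, ...]]
    base_proportions: np.ndarray
    group_effects: np.ndarray
    contaminant_indices: list[int]
    control_proportions: np.ndarray
    n_per_group: int = 4
    reads_per_sample: int = 10_000
    overdispersion: float = 0.01
    similarity_floor: float = 90.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_proportions = np.asarray(self.base_proportions, dtype=float)
        self.group_effects = np.asarray(self.group_effects, dtype=float)
        self.control_proportions = np.asarray(self.control_proportions, dtype=float)
        n = len(self.taxa)
        if any(len(lin) != len(RANKS) for lin in self.taxa):
            raise DesignError("each lineage must have exactly 7 ranks")
        if self.base_proportions.shape != (n,) or self.group_effects.shape != (n,):
            raise DesignError("proportions/effects must match the taxa list")
        if abs(self.base_proportions.sum() - 1.0) > 1e-9:
            raise DesignError("base proportions must sum to 1")
        if (self.group_effects <= 0).any():
            raise DesignError("fold-changes must be positive")
        if len(self.control_proportions) != len(self.contaminant_indices):
            raise DesignError("one control proportion per contaminant taxon")
        if self.contaminant_indices and abs(self.control_proportions.sum() - 1.0) > 1e-9:
            raise DesignError("control proportions must sum to 1")
        if self.n_per_group < 1:
            raise DesignError("n_per_group must be >= 1")
        if not 0 <= self.overdispersion:
            raise DesignError("overdispersion must be non-negative")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def genera(self) -> list[str]:
        return [lin[5] for lin in self.taxa]

    @property
    def planted_differential_genera(self) -> list[str]:
        return sorted(
            {g for g, e in zip(self.genera, self.group_effects) if e != 1.0}
        )

    def expected_proportions(self, group: str) -> np.ndarray:
        """Expected taxon proportions for a group label."""
        if group == MODERATE:
            return self.base_proportions
        if group == SEVERE:
            weighted = self.base_proportions * self.group_effects
            return weighted / weighted.sum()
        if group == CONTROL:
            p = np.zeros(self.n_taxa)
            p[self.contaminant_indices] = self.control_proportions
            return p
        raise ValueError(f"unknown group label: {group!r}")

    def to_yaml(self, path) -> None:
        payload = {
            "taxa": [list(lin) for lin in self.taxa],
            "base_proportions": self.base_proportions.tolist(),
            "group_effects": self.group_effects.tolist(),
            "contaminant_indices": list(self.contaminant_indices),
            "control_proportions": self.control_proportions.tolist(),
            "n_per_group": self.n_per_group,
            "reads_per_sample": self.reads_per_sample,
            "overdispersion": self.overdispersion,
            "similarity_floor": self.similarity_floor,
            "read_length": self.read_length,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityDesign":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["taxa"] = [tuple(lin) for lin in payload["taxa"]]
        return cls(**payload)


def _synthetic_lineage(i: int) -> tuple[str, ...]:
    return (
        "Bacteria", f"Phylum{i}", f"Class{i}", f"Order{i}",
        f"Family{i}", f"Genus{i}", f"Genus{i} sp{i}",
    )


def make_design(
    n_taxa: int = 20,
    n_contaminants: int = 2,
    effect_size: float = 4.0,
    seed: int = 0,
    n_per_group: int = 4,
    reads_per_sample: int = 10_000,
    overdispersion: float = 0.01,
    similarity_floor: float = 90.0,
    min_planted_abundance: float = 0.05,
) -> CommunityDesign:
    """Build a two-group community design with planted differential genera.

    ``n_taxa`` lineages are drawn from the community and contaminant
    pools (contaminants are part of the community at trace abundance
    and dominate the negative control).  Two planted genera carry the
    group effect: one up (fold ``effect_size``) and one down (fold
    ``1/effect_size``) in the severe group, both guaranteed a base
    abundance of at least ``min_planted_abundance`` so the effect is
    observable.  ``effect_size=1`` plants nothing.
    """
    if n_taxa < 5:
        raise DesignError("n_taxa must be >= 5")
    if effect_size <= 0:
        raise DesignError("effect_size must be positive")
    if n_contaminants >= n_taxa:
        raise DesignError("n_contaminants must be smaller than n_taxa")
    if n_contaminants > len(_CONTAMINANT_POOL):
        raise DesignError(
            f"at most {len(_CONTAMINANT_POOL)} contaminant lineages available"
        )

    rng = np.random.default_rng(seed)
    n_community = n_taxa - n_contaminants
    community = list(_COMMUNITY_POOL[:n_community])
    for i in range(len(community), n_community):
        community.append(_synthetic_lineage(i + 1))
    contaminants = _CONTAMINANT_POOL[:n_contaminants]
    taxa = community + list(contaminants)
    contaminant_indices = list(range(n_community, n_taxa))

    # Gamma weights give a realistic uneven community; contaminants are
    # down-weighted to trace level in patient samples.
    weights = rng.gamma(shape=2.0, scale=1.0, size=n_taxa)
    weights[contaminant_indices] *= 0.01
    props = weights / weights.sum()

    effects = np.ones(n_taxa)
    if effect_size != 1.0:
        # plant on the two most abundant community taxa, one up, one down
        order = np.argsort(props[:n_community])[::-1]
        up, down = int(order[0]), int(order[1])
        for idx in (up, down):
            if props[idx] < min_planted_abundance:
                deficit = min_planted_abundance - props[idx]
                props[idx] += deficit
        props = props / props.sum()
        effects[up] = effect_size
        effects[down] = 1.0 / effect_size

    raw_control = rng.dirichlet(np.full(n_contaminants, 5.0)) if n_contaminants else np.array([])
    return CommunityDesign(
        taxa=taxa,
        base_proportions=props,
        group_effects=effects,
        contaminant_indices=contaminant_indices,
        control_proportions=raw_control,
        n_per_group=n_per_group,
        reads_per_sample=reads_per_sample,
        overdispersion=overdispersion,
        similarity_floor=similarity_floor,
        seed=seed,
    )


def sample_counts(
    design: CommunityDesign,
    group: str,
    seed: int | np.random.Generator | None = None,
    overdispersion: float | None = None,
) -> np.ndarray:
    """Draw one sample's per-taxon read counts.

    Dirichlet-multinomial: proportions are jittered by a Dirichlet draw
    with concentration ``p / overdispersion`` before the multinomial;
    overdispersion 0 uses the expected proportions directly.  Counts
    sum to ``design.reads_per_sample``; taxa with zero expected
    proportion (e.g. community taxa in a control sample) never receive
    reads.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = design.overdispersion if overdispersion is None else overdispersion
    p = design.expected_proportions(group)
    support = p > 0
    q = p.copy()
    if theta > 0:
        q[support] = rng.dirichlet(p[support] / theta)
    counts = np.zeros(design.n_taxa, dtype=np.int64)
    counts[support] = rng.multinomial(design.reads_per_sample, q[support] / q[support].sum())
    return counts


def generate_barcodes(
    n: int, length: int = 8, min_distance: int = 5, seed: int = 0
) -> list[str]:
    """Deterministic barcodes with pairwise Hamming distance >= min_distance.

    Distance 5 makes <=2-mismatch demultiplexing unambiguous by
    construction.  Greedy seeded search; raises if it cannot place
    ``n`` codes (generous retry budget, never hit for realistic n).
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    codes: list[str] = []
    attempts = 0
    while len(codes) < n:
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError("could not construct enough distant barcodes")
        cand = "".join(rng.choice(alphabet, size=length))
        if all(
            sum(a != b for a, b in zip(cand, c)) >= min_distance for c in codes
        ):
            codes.append(cand)
    return codes


def _random_bases(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _quality_string(rng: np.random.Generator, length: int, mean_q: float) -> list[int]:
    q = np.clip(np.round(rng.normal(mean_q, 3.0, size=length)), 2, 41)
    return [int(v) for v in q]


def emit_reads(
    counts: np.ndarray,
    barcode: str,
    taxa: list[tuple[str, ...]],
    fastq_path,
    assignment_path,
    sample_id: str,
    seed: int = 0,
    similarity_floor: float = 90.0,
    read_length: int = 150,
    mean_quality: float = 35.0,
    corruption: float = 0.0,
    corruption_modes=CORRUPTION_MODES,
    multihit_fraction: float = 0.0,
) -> pd.DataFrame:
    """Write one sample's FASTQ and truth assignment table.

    Each read gets the sample barcode prepended and a truth assignment
    row (reference id, similarity drawn in ``[similarity_floor, 100]``,
    full lineage).  A ``corruption`` fraction of reads is spoiled by a
    randomly chosen mode: shorter than 70 bp, containing N bases, mean
    quality below 20, or similarity below the floor.  A
    ``multihit_fraction`` of clean reads receives a second
    supra-threshold assignment to a different reference, exercising the
    unique-read rule.  Same seed, same bytes.
    """
    if set(barcode.upper()) - set("ACGT"):
        raise ValueError("barcode must be over A/C/G/T")
    counts = np.asarray(counts, dtype=np.int64)
    rng = np.random.default_rng(seed)
    support = [int(i) for i in np.flatnonzero(counts)]
    rows = []
    read_no = 0
    with open(fastq_path, "w") as fq:
        for taxon_idx in range(len(counts)):
            lineage = taxa[taxon_idx]
            ref_id = f"gi|{100000 + taxon_idx}"
            for _ in range(int(counts[taxon_idx])):
                read_id = f"{sample_id}_r{read_no:06d}"
                read_no += 1
                length = read_length
                similarity = float(rng.uniform(similarity_floor, 100.0))
                mean_q = mean_quality
                n_positions: np.ndarray | None = None

                if corruption > 0 and rng.random() < corruption:
                    mode = corruption_modes[rng.integers(0, len(corruption_modes))]
                    if mode == "short":
                        length = int(rng.integers(30, 70))
                    elif mode == "ambiguous":
                        n_positions = rng.integers(0, length, size=rng.integers(1, 4))
                    elif mode == "low_quality":
                        mean_q = 12.0
                    elif mode == "low_similarity":
                        similarity = float(rng.uniform(50.0, similarity_floor - 0.1))
                    else:
                        raise ValueError(f"unknown corruption mode: {mode!r}")

                bases = list(_random_bases(rng, length))
                if n_positions is not None:
                    for pos in n_positions:
                        bases[int(pos)] = "N"
                seq = barcode + "".join(bases)
                quals = _quality_string(rng, len(seq), mean_q)
                fq.write(f"@{read_id}\n{seq}\n+\n")
                fq.write("".join(chr(q + 33) for q in quals) + "\n")

                rows.append((read_id, ref_id, round(similarity, 2), *lineage))
                # secondary hits stay within the sample's own community so a
                # control sample never gains spurious community assignments
                if (
                    multihit_fraction > 0
                    and len(support) > 1
                    and rng.random() < multihit_fraction
                ):
                    other = support[(support.index(taxon_idx) + 1) % len(support)]
                    rows.append(
                        (
                            read_id,
                            f"gi|{100000 + other}",
                            round(float(rng.uniform(similarity_floor, 100.0)), 2),
                            *taxa[other],
                        )
                    )
    table = pd.DataFrame(
        rows, columns=["read_id", "ref_id", "similarity", *RANKS]
    )
    table.to_csv(assignment_path, sep="\t", index=False)
    return table


@dataclass
class TruthBundle:
    """Paths and ground truth for one simulated cohort."""

    design: CommunityDesign
    fastq_paths: dict[str, Path]
    assignment_paths: dict[str, Path]
    metadata_path: Path
    barcode_path: Path
    multiplexed_fastq: Path
    true_counts: pd.DataFrame = field(repr=False)
    barcodes: dict[str, str] = field(default_factory=dict)

    @property
    def planted_differential_genera(self) -> list[str]:
        return self.design.planted_differential_genera

    @property
    def groups(self) -> pd.Series:
        meta = pd.read_csv(self.metadata_path, sep="\t", index_col="sample_id")
        return meta["group"]


def generate_cohort(
    design: CommunityDesign,
    outdir,
    corruption: float = 0.0,
    multihit_fraction: float = 0.0,
    include_control: bool = True,
) -> TruthBundle:
    """Simulate a full cohort to disk: FASTQs, truth tables, metadata.

    Produces ``n_per_group`` samples per patient group plus (by
    default) one negative control, each with its own barcode, FASTQ and
    truth assignment table, along with a combined multiplexed FASTQ, a
    barcode map and a metadata table.  Fully determined by
    ``design.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = [f"{MODERATE}_{i + 1}" for i in range(design.n_per_group)]
    samples += [f"{SEVERE}_{i + 1}" for i in range(design.n_per_group)]
    if include_control:
        samples.append(f"{CONTROL}_1")

    codes = generate_barcodes(len(samples), seed=design.seed)
    barcodes = dict(zip(samples, codes))
    seeds = np.random.SeedSequence(design.seed).spawn(len(samples))

    fastq_paths, assignment_paths, meta_rows, count_rows = {}, {}, [], {}
    for sample, child in zip(samples, seeds):
        group = sample.rsplit("_", 1)[0]
        rng = np.random.default_rng(child)
        counts = sample_counts(design, group, seed=rng)
        count_rows[sample] = counts
        fq = outdir / f"{sample}.fastq"
        tsv = outdir / f"{sample}.assignments.tsv"
        emit_reads(
            counts,
            barcodes[sample],
            design.taxa,
            fq,
            tsv,
            sample_id=sample,
            seed=int(rng.integers(0, 2**31)),
            similarity_floor=design.similarity_floor,
            read_length=design.read_length,
            corruption=corruption,
            multihit_fraction=multihit_fraction,
        )
        fastq_paths[sample] = fq
        assignment_paths[sample] = tsv
        meta_rows.append(
            {"sample_id": sample, "group": group, "is_control": group == CONTROL}
        )

    multiplexed = outdir / "run.fastq"
    with open(multiplexed, "w") as out:
        for sample in samples:
            out.write(fastq_paths[sample].read_text())

    metadata_path = outdir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)
    barcode_path = outdir / "barcodes.tsv"
    pd.DataFrame(
        {"sample_id": samples, "barcode": [barcodes[s] for s in samples]}
    ).to_csv(barcode_path, sep="\t", index=False)
    design.to_yaml(outdir / "design.yaml")

    true_counts = pd.DataFrame(count_rows, index=design.genera).T
    true_counts.index.name = "sample"
    return TruthBundle(
        design=design,
        fastq_paths=fastq_paths,
        assignment_paths=assignment_paths,
        metadata_path=metadata_path,
        barcode_path=barcode_path,
        multiplexed_fastq=multiplexed,
        true_counts=true_counts,
        barcodes=barcodes,
    )
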