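"""Synthetic cohort generator: designs, count models, read emission."""

import numpy as np
import pandas as pd
import pytest

import metasputum as ms
from metasputum.synthetic import CONTROL, MODERATE, SEVERE


LIN = ("Bacteria", "P", "C", "O", "F", "G", "G s")


class TestMakeDesign:
    def test_constructor_contract(self):
        d = ms.make_design(n_taxa=20, n_contaminants=2, effect_size=4, seed=1)
        assert d.n_taxa == 20
        assert len(d.contaminant_indices) == 2
        assert len(d.planted_differential_genera) >= 2
        assert d.base_proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.control_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identity_effect_plants_nothing(self):
        d = ms.make_design(n_taxa=20, n_contaminants=2, effect_size=1, seed=1)
        assert d.planted_differential_genera == []
        assert (d.group_effects == 1).all()

    def test_all_contaminants_rejected(self):
        with pytest.raises(ms.DesignError):
            ms.make_design(n_taxa=5, n_contaminants=5)

    def test_planted_genera_sufficiently_abundant(self):
        d = ms.make_design(n_taxa=20, effect_size=4, seed=3)
        planted = [i for i, e in enumerate(d.group_effects) if e != 1.0]
        assert (d.base_proportions[planted] >= 0.05).all()

    def test_effects_up_and_down(self):
        d = ms.make_design(n_taxa=20, effect_size=4, seed=2)
        effects = d.group_effects[d.group_effects != 1.0]
        assert set(np.round(effects, 9)) == {4.0, 0.25}

    def test_yaml_round_trip(self, tmp_path, design):
        path = tmp_path / "design.yaml"
        design.to_yaml(path)
        back = ms.CommunityDesign.from_yaml(path)
        assert back.taxa == design.taxa
        np.testing.assert_allclose(back.base_proportions, design.base_proportions)
        assert back.seed == design.seed


class TestSampleCounts:
    def test_single_taxon_gets_all_reads(self):
        d = ms.CommunityDesign(
            taxa=[LIN], base_proportions=[1.0], group_effects=[1.0],
            contaminant_indices=[], control_proportions=[],
            reads_per_sample=500,
        )
        counts = ms.sample_counts(d, MODERATE, seed=0)
        assert counts.tolist() == [500]

    def test_counts_sum_to_depth(self, design):
        for group in (MODERATE, SEVERE, CONTROL):
            counts = ms.sample_counts(design, group, seed=1)
            assert counts.sum() == design.reads_per_sample

    def test_control_restricted_to_contaminants(self, design):
        counts = ms.sample_counts(design, CONTROL, seed=2)
        community = np.setdiff1d(
            np.arange(design.n_taxa), design.contaminant_indices
        )
        assert (counts[community] == 0).all()
        assert counts[design.contaminant_indices].sum() == design.reads_per_sample

    def test_unknown_group_rejected(self, design):
        with pytest.raises(ValueError, match="unknown group"):
            ms.sample_counts(design, "mild", seed=0)

    def test_multinomial_limit_matches_binomial_oracle(self, design):
        """At overdispersion 0, counts track the binomial expectation:
        every taxon within 4 SDs and the bulk within 3."""
        n = 10_000
        d = ms.make_design(n_taxa=20, seed=11, reads_per_sample=n, overdispersion=0.0)
        counts = ms.sample_counts(d, MODERATE, seed=4, overdispersion=0.0)
        p = d.expected_proportions(MODERATE)
        sd = np.sqrt(n * p * (1 - p))
        z = np.abs(counts - n * p) / sd
        assert (z <= 4).all()
        assert (z <= 3).mean() >= 0.9

    def test_severe_expectation_renormalized(self, design):
        p = design.expected_proportions(SEVERE)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        weighted = design.base_proportions * design.group_effects
        np.testing.assert_allclose(p, weighted / weighted.sum())


class TestEmitReads:
    def test_three_clean_reads(self, tmp_path):
        table = ms.emit_reads(
            np.array([3]), "ACGTACGT", [LIN],
            tmp_path / "x.fastq", tmp_path / "x.tsv",
            sample_id="s", seed=0, corruption=0.0,
        )
        reads = list(ms.read_fastq(tmp_path / "x.fastq"))
        assert len(reads) == 3
        assert len(table) == 3
        assert (table["genus"] == "G").all()
        assert (table["similarity"] >= 90).all()

    def test_forced_short_corruption(self, tmp_path):
        barcode = "ACGTACGT"
        ms.emit_reads(
            np.array([50]), barcode, [LIN],
            tmp_path / "x.fastq", tmp_path / "x.tsv",
            sample_id="s", seed=1, corruption=1.0, corruption_modes=("short",),
        )
        for read in ms.read_fastq(tmp_path / "x.fastq"):
            assert len(read) - len(barcode) < 70

    def test_empty_counts_empty_outputs(self, tmp_path):
        table = ms.emit_reads(
            np.array([], dtype=int), "ACGTACGT", [],
            tmp_path / "x.fastq", tmp_path / "x.tsv", sample_id="s",
        )
        assert table.empty
        assert (tmp_path / "x.fastq").read_text() == ""

    def test_deterministic_bytes(self, tmp_path):
        for tag in ("a", "b"):
            ms.emit_reads(
                np.array([20, 10]), "ACGTACGT", [LIN, LIN],
                tmp_path / f"{tag}.fastq", tmp_path / f"{tag}.tsv",
                sample_id="s", seed=7, corruption=0.3,
            )
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_invalid_barcode_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="barcode"):
            ms.emit_reads(np.array([1]), "ACGTN", [LIN],
                          tmp_path / "x.fastq", tmp_path / "x.tsv", "s")


class TestCohort:
    def test_regeneration_is_byte_identical(self, design, tmp_path):
        a = ms.generate_cohort(design, tmp_path / "a", corruption=0.1)
        b = ms.generate_cohort(design, tmp_path / "b", corruption=0.1)
        assert a.multiplexed_fastq.read_bytes() == b.multiplexed_fastq.read_bytes()
        for sample in a.assignment_paths:
            assert (
                a.assignment_paths[sample].read_bytes()
                == b.assignment_paths[sample].read_bytes()
            )

    def test_metadata_layout(self, cohort_bundle):
        meta = pd.read_csv(cohort_bundle.metadata_path, sep="\t")
        assert set(meta.columns) == {"sample_id", "group", "is_control"}
        assert meta["is_control"].sum() == 1
        assert (meta["group"].value_counts()[["moderate", "severe"]] == 4).all()

    def test_control_assignments_only_contaminants(self, cohort_bundle, design):
        df = ms.read_assignments(cohort_bundle.assignment_paths["control_1"])
        contaminant_genera = {design.taxa[i][5] for i in design.contaminant_indices}
        assert set(df["genus"]) <= contaminant_genera

    def test_read_ids_unique_within_assignment_tables(self, clean_bundle):
        for path in clean_bundle.assignment_paths.values():
            df = ms.read_assignments(path)
            assert df["read_id"].is_unique

    def test_planted_genera_exist_in_taxa(self, cohort_bundle):
        genera = set(cohort_bundle.design.genera)
        assert set(cohort_bundle.planted_differential_genera) <= genera


class TestBarcodes:
    def test_pairwise_distance_at_least_five(self):
        codes = ms.generate_barcodes(9, seed=0)
        assert len(codes) == 9
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                assert sum(x != y for x, y in zip(a, b)) >= 5

    def test_deterministic(self):
        assert ms.generate_barcodes(5, seed=3) == ms.generate_barcodes(5, seed=3)


def test_effect_size_recovery():
    """Severe/moderate abundance ratio of the up-planted genus matches the
    design's renormalized fold-change over replicate cohorts."""
    d = ms.make_design(n_taxa=20, effect_size=4.0, seed=5,
                       reads_per_sample=5000, overdispersion=0.005)
    up_idx = int(np.argmax(d.group_effects))
    z = float((d.base_proportions * d.group_effects).sum())
    rng = np.random.default_rng(99)
    ratios = []
    for _ in range(40):
        mod = np.mean([
            ms.sample_counts(d, MODERATE, seed=rng)[up_idx] / d.reads_per_sample
            for _ in range(4)
        ])
        sev = np.mean([
            ms.sample_counts(d, SEVERE, seed=rng)[up_idx] / d.reads_per_sample
            for _ in range(4)
        ])
        ratios.append(sev / mod)
    assert np.mean(ratios) == pytest.approx(4.0 / z, rel=0.1)
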