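"""Unique-read selection, group-common genera, and CV-quartile filtering."""

import numpy as np
import pandas as pd
import pytest

import metasputum as ms
from metasputum.profiling import RANKS


def asn(read_id, ref_id, similarity, genus="Rothia"):
    return {
        "read_id": read_id, "ref_id": ref_id, "similarity": similarity,
        "kingdom": "Bacteria", "phylum": "P", "class": "C", "order": "O",
        "family": "F", "genus": genus, "species": f"{genus} sp",
    }


def frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "ref_id", "similarity", *RANKS])


class TestSelectUniqueReads:
    def test_single_hit_above_threshold_retained(self):
        df = frame([asn("r1", "gi|1", 96.0)])
        assert len(ms.select_unique_reads(df, 95)) == 1

    def test_two_supra_threshold_hits_excluded(self):
        df = frame([asn("r1", "gi|1", 96.0), asn("r1", "gi|2", 97.0)])
        assert ms.select_unique_reads(df, 95).empty

    def test_sub_threshold_hit_does_not_count(self):
        df = frame([asn("r1", "gi|1", 94.0), asn("r1", "gi|2", 96.0)])
        out = ms.select_unique_reads(df, 95)
        assert out["ref_id"].tolist() == ["gi|2"]

    def test_subset_of_similarity_filter(self, cohort_bundle):
        df = ms.read_assignments(cohort_bundle.assignment_paths["moderate_1"])
        unique = ms.select_unique_reads(df, 90)
        filtered_ids = set(ms.filter_by_similarity(df, 90)["read_id"])
        assert set(unique["read_id"]) <= filtered_ids
        assert unique["read_id"].is_unique


class TestGroupCommonGenera:
    def table(self, counts):
        df = pd.DataFrame(counts)
        groups = pd.Series("g1", index=df.index)
        return ms.AbundanceTable(df, rank="genus", groups=groups)

    def test_present_everywhere_retained(self):
        out = ms.group_common_genera(self.table({"A": [3, 5, 2, 8]}))
        assert out["g1"] == ["A"]

    def test_one_zero_sample_excludes(self):
        out = ms.group_common_genera(self.table({"A": [3, 0, 2, 8]}))
        assert out["g1"] == []

    def test_all_zero_excluded(self):
        out = ms.group_common_genera(self.table({"A": [0, 0, 0, 0]}))
        assert out["g1"] == []


class TestCvQuartileFilter:
    def records(self, cvs, group="g1"):
        return pd.DataFrame(
            {
                "group": group,
                "genus": [f"t{i:02d}" for i in range(len(cvs))],
                "mean": 10.0,
                "sd": [cv * 10.0 for cv in cvs],
                "cv": cvs,
            }
        )

    def test_lowest_quartile_retained(self):
        out = ms.cv_quartile_filter(self.records([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]))
        kept = sorted(out.loc[out["retained"], "cv"])
        assert kept == [0.1, 0.2]

    def test_all_equal_cvs_all_retained(self):
        out = ms.cv_quartile_filter(self.records([0.3] * 8))
        assert out["retained"].all()
        assert (out["quartile_bin"] == 1).all()

    def test_constant_counts_cv_zero_always_retained(self):
        out = ms.cv_quartile_filter(self.records([0.0, 0.5, 0.6, 0.7, 0.8]))
        assert out.loc[out["cv"] == 0.0, "retained"].all()

    def test_fewer_than_four_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            out = ms.cv_quartile_filter(self.records([0.1, 0.9]))
        assert out["retained"].all()

    def test_retained_count_near_quarter(self):
        rng = np.random.default_rng(0)
        for n in (4, 5, 7, 8, 12, 17):
            out = ms.cv_quartile_filter(self.records(list(rng.uniform(0, 1, n))))
            kept = int(out["retained"].sum())
            assert abs(kept - n / 4) <= 1

    def test_groups_filtered_independently(self):
        recs = pd.concat(
            [self.records([0.1, 0.2, 0.3, 0.4], "g1"),
             self.records([1.1, 1.2, 1.3, 1.4], "g2")],
            ignore_index=True,
        )
        out = ms.cv_quartile_filter(recs)
        for g in ("g1", "g2"):
            sub = out[out["group"] == g]
            assert sub.loc[sub["retained"], "cv"].tolist() == [sub["cv"].min()]


def test_cv_scale_invariance():
    counts = pd.DataFrame({"A": [3, 5, 2, 8], "B": [30, 50, 20, 80]})
    groups = pd.Series("g1", index=counts.index)
    table = ms.AbundanceTable(counts, rank="genus", groups=groups)
    recs = ms.consensus_records(table).set_index("genus")
    assert recs.loc["A", "cv"] == pytest.approx(recs.loc["B", "cv"], rel=1e-12)


def test_consensus_records_use_n_minus_one_sd():
    counts = pd.DataFrame({"A": [1, 2, 3, 4]})
    table = ms.AbundanceTable(counts, rank="genus",
                              groups=pd.Series("g", index=counts.index))
    recs = ms.consensus_records(table)
    assert recs["sd"].iloc[0] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
    assert recs["cv"].iloc[0] == pytest.approx(recs["sd"].iloc[0] / 2.5)


class TestRankUniqueDifferences:
    def setup_table(self):
        counts = pd.DataFrame(
            {
                # stable in both groups, big difference
                "Stable": [100, 110, 90, 100, 400, 410, 390, 400],
                # equal effect size but wildly variable in both groups
                "Noisy": [5, 300, 10, 85, 700, 5, 500, 395],
                # equal means
                "Flat": [50, 50, 50, 50, 50, 50, 50, 50],
                "Fill1": [10, 11, 9, 10, 12, 11, 10, 13],
                "Fill2": [20, 22, 18, 20, 19, 21, 20, 22],
            }
        )
        groups = pd.Series(["moderate"] * 4 + ["severe"] * 4, index=counts.index)
        return ms.AbundanceTable(counts, rank="genus", groups=groups)

    def test_arithmetic_and_direction(self):
        table = self.setup_table()
        recs = ms.cv_quartile_filter(ms.consensus_records(table))
        out = ms.rank_unique_differences(recs, table, top_n=10)
        row = out.set_index("genus").loc["Stable"]
        assert row["mean_moderate"] == 100.0
        assert row["mean_severe"] == 400.0
        assert row["difference"] == -300.0

    def test_equal_means_difference_zero(self):
        table = self.setup_table()
        recs = ms.cv_quartile_filter(ms.consensus_records(table))
        recs.loc[recs["genus"] == "Flat", "retained"] = True
        out = ms.rank_unique_differences(recs, table, top_n=10).set_index("genus")
        assert out.loc["Flat", "difference"] == 0.0

    def test_high_cv_genus_removed_by_filter(self):
        """A planted low-CV genus outranks an equal-effect high-CV genus."""
        table = self.setup_table()
        recs = ms.cv_quartile_filter(ms.consensus_records(table))
        retained = set(recs.loc[recs["retained"], "genus"])
        assert "Stable" in retained or "Fill1" in retained
        assert "Noisy" not in retained
        out = ms.rank_unique_differences(recs, table, top_n=10)
        assert "Noisy" not in set(out["genus"])

    def test_empty_retained_set_warns(self):
        table = self.setup_table()
        recs = ms.consensus_records(table)
        recs["retained"] = False
        with pytest.warns(UserWarning, match="no genera retained"):
            out = ms.rank_unique_differences(recs, table)
        assert out.empty

    def test_intersection_mode_subset_of_union(self):
        table = self.setup_table()
        recs = ms.cv_quartile_filter(ms.consensus_records(table))
        union = ms.rank_unique_differences(recs, table, top_n=100, mode="union")
        inter = ms.rank_unique_differences(recs, table, top_n=100, mode="intersection")
        assert set(inter["genus"]) <= set(union["genus"])


def test_pipeline_absent_genus_never_retained(patient_assignments, patient_groups):
    records, _ = ms.consensus_analysis(
        patient_assignments, patient_groups, 90.0, top_n=10
    )
    table = ms.unique_read_table(patient_assignments, 90.0, groups=patient_groups)
    for _, rec in records.iterrows():
        block = table.counts.loc[table.groups == rec["group"], rec["genus"]]
        assert (block > 0).all()
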