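"""Fusion consensus, filtering, annotation and summary tests."""
import numpy as np
import pandas as pd
import pytest

from gistint.errors import AnnotationError, DomainError
from gistint.fixtures import (load_candidate_fusion_table,
                              load_clinical_table, load_fusion_count_table,
                              per_sample_fusion_totals)
from gistint.fusions import (annotate_readthrough, classify_recurrence,
                             filter_fusion_support,
                             flag_partner_overexpression,
                             interchromosomal_counts, is_readthrough,
                             merge_all_samples, merge_caller_outputs,
                             summarize_fusions_by_group)
from gistint.io import sample_groups
from gistint.models import ExpressionMatrix


class TestMerge:
    def test_union_semantics_with_tool_provenance(self, fusion_calls):
        merged = merge_caller_outputs(fusion_calls)
        ab = merged[merged["gene3"] == "B"].iloc[0]
        ac = merged[merged["gene3"] == "C"].iloc[0]
        assert ab["tools"] == "CS,DF"
        assert ab["spanning_pairs"] == 5 and ab["junction_reads"] == 4
        assert ac["tools"] == "DF"   # single-tool records are retained

    def test_empty_input(self):
        assert merge_caller_outputs(pd.DataFrame(
            columns=["sample", "caller", "gene5", "gene3"])).empty

    def test_mixed_samples_raise(self, fusion_calls):
        bad = fusion_calls.copy()
        bad.loc[0, "sample"] = "s2"
        with pytest.raises(DomainError):
            merge_caller_outputs(bad)

    def test_merge_is_idempotent(self, fusion_calls):
        once = merge_caller_outputs(fusion_calls)
        twice = merge_caller_outputs(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSupportFilter:
    @pytest.mark.parametrize("spanning,junction,kept", [
        (2, 1, True), (3, 0, False), (1, 4, False), (10, 10, True)])
    def test_both_thresholds_required(self, spanning, junction, kept):
        fus = pd.DataFrame({"spanning_pairs": [spanning],
                            "junction_reads": [junction]})
        assert (len(filter_fusion_support(fus)) == 1) is kept

    def test_raising_min_pairs_is_anti_monotone(self):
        rng = np.random.default_rng(3)
        fus = pd.DataFrame({"spanning_pairs": rng.integers(0, 10, 50),
                            "junction_reads": rng.integers(0, 5, 50)})
        sizes = [len(filter_fusion_support(fus, min_pairs=m))
                 for m in range(8)]
        assert sizes == sorted(sizes, reverse=True)


class TestReadthrough:
    def test_adjacent_same_strand_pair(self, toy_gene_models):
        assert is_readthrough("A", "B", toy_gene_models) is True

    def test_interchromosomal_pair(self, toy_gene_models):
        assert is_readthrough("A", "E", toy_gene_models) is False

    def test_opposite_strand_neighbour(self, toy_gene_models):
        assert is_readthrough("A", "D", toy_gene_models) is False

    def test_not_nearest_downstream(self, toy_gene_models):
        assert is_readthrough("A", "C", toy_gene_models) is False

    def test_gap_cap(self, toy_gene_models):
        assert is_readthrough("B", "C", toy_gene_models,
                              max_gap=200_000) is False

    def test_unknown_gene_raises(self, toy_gene_models):
        with pytest.raises(AnnotationError, match="nope"):
            is_readthrough("A", "nope", toy_gene_models)

    def test_annotate_adds_column(self, toy_gene_models):
        fus = pd.DataFrame({"gene5": ["A", "A"], "gene3": ["B", "C"]})
        out = annotate_readthrough(fus, toy_gene_models)
        assert list(out["read_through"]) == [True, False]


class TestRecurrence:
    def test_private_versus_recurrent(self):
        consensus = pd.DataFrame({
            "sample": ["s1", "s1", "s2", "s2", "s3"],
            "gene5": ["A", "X", "A", "Y", "A"],
            "gene3": ["B", "Z", "B", "Z2", "B"]})
        pairs, per_sample = classify_recurrence(consensus)
        ab = pairs[(pairs["gene5"] == "A")].iloc[0]
        assert ab["n_samples"] == 3 and bool(ab["recurrent"])
        s1 = per_sample.set_index("sample")
        assert s1.loc["s1", "private"] == 1
        assert s1.loc["s1", "recurrent"] == 1
        # totals per sample add up to the consensus records counted once
        assert s1["total"].sum() == len(consensus)

    def test_single_sample_cohort_all_private(self):
        consensus = pd.DataFrame({"sample": ["s1"] * 3,
                                  "gene5": ["A", "B", "C"],
                                  "gene3": ["X", "Y", "Z"]})
        pairs, _ = classify_recurrence(consensus)
        assert not pairs["recurrent"].any()

    def test_duplicate_records_count_once_per_sample(self):
        consensus = pd.DataFrame({"sample": ["s1", "s1"],
                                  "gene5": ["A", "A"], "gene3": ["B", "B"]})
        pairs, per_sample = classify_recurrence(consensus)
        assert pairs.iloc[0]["n_samples"] == 1
        assert per_sample.iloc[0]["total"] == 1


class TestCuratedCohortTables:
    def test_recurrent_readthroughs(self):
        pairs, _ = classify_recurrence(load_candidate_fusion_table())
        counts = pairs.set_index(["gene5", "gene3"])["n_samples"]
        assert counts[("POLA2", "CDC42EP2")] == 7
        assert counts[("C8orf42", "FBXO25")] == 4
        assert counts[("STX16", "NPEPL1")] == 3

    def test_group_summaries(self):
        totals = per_sample_fusion_totals()
        groups = sample_groups(load_clinical_table())
        summary = summarize_fusions_by_group(totals, groups) \
            .set_index("group")
        assert summary.loc["gastric_kit_mutant", "mean"] == 82.0
        assert (summary.loc["gastric_kit_mutant", ["min", "max"]].tolist()
                == [68, 109])
        assert summary.loc["small_intestine", "mean"] == 49.5
        assert summary.loc["wild_type", "mean"] == 33.0
        assert summary.loc["wild_type", ["min", "max"]].tolist() == [25, 41]

    def test_private_totals(self):
        counts = load_fusion_count_table()
        assert counts["private_fusions"].sum() == 228
        assert counts["private_fusions"].max() == 63

    def test_unlabelled_sample_raises(self):
        with pytest.raises(DomainError):
            summarize_fusions_by_group({"s1": 5}, {})

    def test_single_sample_group_mean(self):
        summary = summarize_fusions_by_group({"s1": 7}, {"s1": "g"})
        assert summary.iloc[0]["mean"] == 7.0


class TestOverexpression:
    def _expr(self):
        values = pd.DataFrame(
            {"s1": [10.0, 6.0, 4.0], "s2": [2.0, 4.0, 4.0],
             "s3": [0.0, 2.0, 4.0]},
            index=["gA", "gB", "gC"])
        return ExpressionMatrix(values, "rpkm")

    def test_fold_change_rule(self):
        fus = pd.DataFrame({"sample": ["s1"], "gene5": ["gA"],
                            "gene3": ["gB"]})
        out = flag_partner_overexpression(fus, self._expr())
        assert bool(out.iloc[0]["overexpressed5"])    # 10 vs mean 4
        assert not out.iloc[0]["overexpressed3"]      # 6 vs mean 4
        assert out.iloc[0]["fold_change5"] == pytest.approx(2.5)

    def test_constant_gene_not_flagged(self):
        fus = pd.DataFrame({"sample": ["s1"], "gene5": ["gC"],
                            "gene3": ["gA"]})
        out = flag_partner_overexpression(fus, self._expr())
        assert not out.iloc[0]["overexpressed5"]

    def test_missing_gene_warns_and_unflags(self):
        fus = pd.DataFrame({"sample": ["s1"], "gene5": ["nope"],
                            "gene3": ["gA"]})
        with pytest.warns(UserWarning, match="nope"):
            out = flag_partner_overexpression(fus, self._expr())
        assert not out.iloc[0]["overexpressed5"]


class TestInterchromosomal:
    def test_symmetric_counts_exclude_readthroughs(self):
        fus = pd.DataFrame({
            "chrom5": ["11", "17", "11", "11"],
            "chrom3": ["17", "11", "11", "11"],
            "read_through": [False, False, False, True]})
        table = interchromosomal_counts(fus).set_index(["chrom_a", "chrom_b"])
        assert table.loc[("11", "17"), "count"] == 2
        assert table.loc[("11", "11"), "count"] == 1

    def test_all_readthrough_gives_empty(self):
        fus = pd.DataFrame({"chrom5": ["11"], "chrom3": ["11"],
                            "read_through": [True]})
        assert interchromosomal_counts(fus).empty

    def test_empty_input(self):
        assert interchromosomal_counts(
            pd.DataFrame(columns=["chrom5", "chrom3"])).empty


def test_merge_all_samples_groups_by_sample(fusion_calls):
    two = pd.concat([fusion_calls,
                     fusion_calls.assign(sample="s2")], ignore_index=True)
    merged = merge_all_samples(two)
    assert set(merged["sample"]) == {"s1", "s2"}
    assert len(merged) == 4
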