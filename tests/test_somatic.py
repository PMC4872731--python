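"""Unit and property tests for the tumor/normal somatic caller."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gistint.errors import DomainError
from gistint.models import ExpressionMatrix
from gistint.somatic import (annotate_calls, annotate_consequence,
                             call_somatic_sites, expression_support,
                             mutation_spectrum, recurrent_mutated_genes,
                             vaf_posterior_diff)


def mc_oracle(t_alt, t_ref, n_alt, n_ref, n_draws=1_000_000, seed=0):
    """Monte-Carlo estimate of P(p_T > p_N) from beta posterior draws."""
    rng = np.random.default_rng(seed)
    pt = rng.beta(t_alt + 1, t_ref + 1, n_draws)
    pn = rng.beta(n_alt + 1, n_ref + 1, n_draws)
    return float((pt > pn).mean())


class TestVafPosteriorDiff:
    def test_symmetric_counts_give_exactly_half(self):
        assert vaf_posterior_diff(5, 5, 5, 5) == 0.5
        assert vaf_posterior_diff(0, 30, 0, 30) == 0.5

    def test_single_read_case_matches_analytic_value(self):
        # Beta(2,1) vs Beta(1,2): double integral evaluates to 5/6
        assert vaf_posterior_diff(1, 0, 0, 1) == pytest.approx(5 / 6,
                                                               abs=1e-12)
        assert mc_oracle(1, 0, 0, 1) == pytest.approx(5 / 6, abs=2e-3)

    def test_clear_somatic_signal_is_near_one(self):
        assert vaf_posterior_diff(25, 25, 0, 50) > 0.999

    def test_zero_depth_raises(self):
        with pytest.raises(DomainError):
            vaf_posterior_diff(0, 0, 5, 5)
        with pytest.raises(DomainError):
            vaf_posterior_diff(5, 5, 0, 0)
        with pytest.raises(DomainError):
            vaf_posterior_diff(-1, 2, 1, 1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40), st.integers(0, 40))
    def test_exchanging_samples_complements_probability(self, ta, tr, na, nr):
        if ta + tr == 0 or na + nr == 0:
            return
        p = vaf_posterior_diff(ta, tr, na, nr)
        q = vaf_posterior_diff(na, nr, ta, tr)
        assert 0.0 <= p <= 1.0
        assert p + q == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_tumor_alt_at_fixed_depth(self):
        depth = 30
        values = [vaf_posterior_diff(a, depth - a, 3, 27)
                  for a in range(depth + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestCallSomaticSites:
    @staticmethod
    def _sites(rows):
        return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref",
                                           "alt", "t_ref", "t_alt", "n_ref",
                                           "n_alt"])

    def test_calling_rules(self):
        sites = self._sites([
            ("s1", "chr1", 100, "A", "T", 25, 25, 50, 0),   # clean somatic
            ("s1", "chr1", 200, "A", "T", 5, 5, 5, 5),      # no VAF shift
            ("s1", "chr1", 300, "A", "T", 30, 30, 32, 28),  # germline het
        ])
        calls = call_somatic_sites(sites, 0.99, 0.03)
        assert list(calls["somatic"]) == [True, False, False]
        assert calls.loc[1, "p_diff"] == 0.5
        # germline site fails only the normal-VAF gate
        assert calls.loc[2, "normal_vaf"] == pytest.approx(28 / 60)

    def test_all_sites_returned_with_p_diff(self):
        sites = self._sites([("s1", "chr1", 1, "A", "T", 10, 0, 10, 0)])
        calls = call_somatic_sites(sites)
        assert len(calls) == 1 and "p_diff" in calls.columns

    def test_bad_thresholds_raise(self):
        sites = self._sites([("s1", "chr1", 1, "A", "T", 10, 0, 10, 0)])
        with pytest.raises(DomainError):
            call_somatic_sites(sites, p_threshold=1.5)


class TestConsequence:
    def test_stop_gain_is_nonsense(self, plus_model):
        # TGG codon at 104-106 -> TGA
        assert annotate_consequence("chr1", 106, "G", "A",
                                    plus_model) == "nonsense"

    def test_third_position_wobble_is_synonymous(self, plus_model):
        # CGT at 301-303 -> CGC, both Arg
        assert annotate_consequence("chr1", 303, "T", "C",
                                    plus_model) == "synonymous"

    def test_first_intronic_base_is_splice_site(self, plus_model):
        assert annotate_consequence("chr1", 191, "T", "A",
                                    plus_model) == "splice_site"
        assert annotate_consequence("chr1", 299, "T", "A",
                                    plus_model) == "splice_site"

    def test_stop_codon_disruption_is_stop_loss(self, plus_model):
        # TAA at 588-590 -> CAA (Gln)
        assert annotate_consequence("chr1", 588, "T", "C",
                                    plus_model) == "stop_loss"

    def test_amino_acid_change_is_missense(self, plus_model):
        # TGG (Trp) -> TGC (Cys)
        assert annotate_consequence("chr1", 106, "G", "C",
                                    plus_model) == "missense"

    def test_cds_indel_and_deep_intron(self, plus_model):
        assert annotate_consequence("chr1", 104, "TG", "T",
                                    plus_model) == "indel"
        assert annotate_consequence("chr1", 250, "T", "A",
                                    plus_model) == "noncoding"

    def test_minus_strand_evaluated_on_reverse_complement(self, minus_model):
        # transcript index 87 (first base of the TAA stop) is genomic 103;
        # genomic A>G reads as transcript T>C, TAA -> CAA: stop loss
        assert minus_model.base_at(103) == "A"
        assert annotate_consequence("chr2", 103, "A", "G",
                                    minus_model) == "stop_loss"
        # transcript index 1 (ATG -> AcG? no: index 1 is T of ATG) is
        # genomic 189; genomic A>C reads as T>G: ATG -> AGG (missense)
        assert annotate_consequence("chr2", 189, "A", "C",
                                    minus_model) == "missense"

    def test_out_of_span_raises(self, plus_model):
        with pytest.raises(DomainError):
            annotate_consequence("chr1", 50, "A", "T", plus_model)


class TestSpectrumAndRecurrence:
    def test_complement_collapsing(self):
        calls = pd.DataFrame({"ref": ["G", "C", "A"],
                              "alt": ["A", "T", "C"]})
        spec = mutation_spectrum(calls)
        assert spec["C>T/G>A"] == 2
        assert spec["T>G/A>C"] == 1
        assert spec.sum() == 3

    def test_empty_and_indel_inputs(self):
        assert mutation_spectrum(pd.DataFrame({"ref": [], "alt": []})).sum() == 0
        calls = pd.DataFrame({"ref": ["AT"], "alt": ["A"]})
        assert mutation_spectrum(calls).sum() == 0

    def test_all_twelve_raw_substitutions_fold_to_pairs(self):
        rows = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        spec = mutation_spectrum(pd.DataFrame(rows, columns=["ref", "alt"]))
        assert (spec == 2).all()

    def test_recurrent_genes_require_protein_altering_calls(self):
        calls = pd.DataFrame({
            "sample": ["s1", "s1", "s2", "s1", "s2", "s3"],
            "gene_id": ["TP53", "KIT", "TP53", "SYN1", "SYN1", "SYN1"],
            "consequence": ["missense", "indel", "nonsense",
                            "synonymous", "synonymous", "synonymous"],
        })
        rec = recurrent_mutated_genes(calls, min_samples=2)
        assert rec.to_dict() == {"TP53": 2}

    def test_once_per_sample_regardless_of_multiplicity(self):
        calls = pd.DataFrame({
            "sample": ["s1", "s1", "s1"],
            "gene_id": ["KIT"] * 3,
            "consequence": ["missense"] * 3,
        })
        assert recurrent_mutated_genes(calls).empty


class TestExpressionSupport:
    def test_inclusive_threshold_and_fraction(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [2.0, 0.5, 1.0, 0.0]},
                         index=["g1", "g2", "g3", "g4"]), "rpkm")
        calls = pd.DataFrame({"sample": ["s1"] * 4,
                              "gene_id": ["g1", "g2", "g3", "g4"]})
        flagged, fraction = expression_support(calls, expr, rpkm_min=1.0)
        assert list(flagged["expressed"]) == [True, False, True, False]
        assert fraction == 0.5

    def test_uncovered_genes_excluded_from_fraction(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [5.0]}, index=["g1"]), "rpkm")
        calls = pd.DataFrame({"sample": ["s1", "s1"],
                              "gene_id": ["g1", "missing"]})
        flagged, fraction = expression_support(calls, expr)
        assert list(flagged["covered"]) == [True, False]
        assert fraction == 1.0


def test_annotate_calls_assigns_only_covered_sites(plus_model):
    sites = pd.DataFrame({
        "sample": ["s1", "s1"], "chrom": ["chr1", "chr9"],
        "pos": [106, 500], "ref": ["G", "A"], "alt": ["A", "T"],
    })
    out = annotate_calls(sites, {"GENEP": plus_model})
    assert out.loc[0, "gene_id"] == "GENEP"
    assert out.loc[0, "consequence"] == "nonsense"
    assert pd.isna(out.loc[1, "gene_id"])
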