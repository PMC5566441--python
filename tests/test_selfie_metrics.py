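import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfiedpcr import (aggregate_replicates, compare_groups, copies_per_genome,
                        integrations_per_genome, percent_difference,
                        rna_copies, silencing_percent, strand_metrics,
                        transcripts_per_gene, transcripts_per_genome)
from selfiedpcr.errors import ContractError
from selfiedpcr.selfie_metrics import SelfieResult


def _result(tpg, se=0.0):
    return SelfieResult(transcripts_per_gene=tpg, se=se, ci_low=tpg - 2 * se,
                        ci_high=tpg + 2 * se, detected=True)


class TestTranscriptsPerGene:
    def test_brain_lysate_pair(self):
        # untreated whole-brain aliquots: 1794 copies with RT, 608 without
        r = transcripts_per_gene(1794.0, 608.0)
        assert round(r.transcripts_per_gene, 2) == 1.95

    def test_equal_aliquots_give_zero(self):
        assert transcripts_per_gene(500.0, 500.0).transcripts_per_gene == 0.0

    def test_rnase_treated_pair_is_negative_and_undetected(self):
        # RNase abolishes the RT+/RT- difference; noise makes it slightly negative
        r = transcripts_per_gene(470.0, 493.0, var_plus=18.0**2, var_minus=4.0**2)
        assert round(r.transcripts_per_gene, 3) == -0.047
        assert not r.detected  # CI spans zero

    def test_zero_gene_copies_rejected(self):
        with pytest.raises(ContractError):
            transcripts_per_gene(100.0, 0.0)

    def test_self_consistency_with_subtraction(self):
        # (RT- * t/g) + RT- reconstructs RT+ exactly
        r = transcripts_per_gene(1794.0, 608.0)
        assert 608.0 * r.transcripts_per_gene + 608.0 == pytest.approx(1794.0)
        copies, _ = rna_copies(1794.0, 608.0)
        assert copies == 608.0 * r.transcripts_per_gene

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_unit_invariance(self, scale):
        # identical on copies/reaction and copies/ul: the ratio cancels volume
        a = transcripts_per_gene(1794.0, 608.0).transcripts_per_gene
        b = transcripts_per_gene(1794.0 * scale, 608.0 * scale).transcripts_per_gene
        assert a == pytest.approx(b, rel=1e-9)

    def test_sign_follows_rt_difference(self):
        assert transcripts_per_gene(500.0, 600.0).transcripts_per_gene < 0
        assert transcripts_per_gene(700.0, 600.0).transcripts_per_gene > 0


class TestRnaCopies:
    def test_subtraction(self):
        value, _ = rna_copies(1794.0, 608.0)
        assert value == 1186.0

    def test_identical_pair_zero(self):
        assert rna_copies(321.0, 321.0)[0] == 0.0

    def test_se_adds_in_quadrature(self):
        _, se = rna_copies(100.0, 50.0, var_plus=9.0, var_minus=16.0)
        assert se == pytest.approx(5.0)


class TestGenomeNormalization:
    def test_identical_single_copy_genes_ratio_one(self):
        g = copies_per_genome(608.0, 608.0)
        assert g.copies_per_genome == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ContractError):
            copies_per_genome(100.0, 0.0)

    def test_transcripts_per_genome_products(self):
        assert transcripts_per_genome(27.0, 107.0) == 2889.0
        assert transcripts_per_genome(3.14, 1.0) == 3.14
        # H-strand transcription x mtDNA copy number, within the replicate band
        assert 549.0 <= transcripts_per_genome(0.55, 1096.0) <= 651.0

    def test_ratio_ci_contains_point(self):
        g = copies_per_genome(1200.0, 600.0, var_target=40.0**2, var_single=20.0**2)
        assert g.ci_low <= g.copies_per_genome <= g.ci_high


class TestStrandMetrics:
    def test_brain_heavy_strand_excess(self):
        rep = strand_metrics(_result(0.55), _result(0.37))
        assert round(rep.percent_excess_h) == 49

    def test_equal_strands_no_excess(self):
        rep = strand_metrics(_result(0.4), _result(0.4))
        assert rep.percent_excess_h == 0.0

    def test_sum_and_consistency_z(self):
        h, l = _result(0.55, 0.03), _result(0.37, 0.02)
        combined = _result(0.92, 0.04)
        rep = strand_metrics(h, l, combined)
        assert rep.total == pytest.approx(0.92)
        assert rep.consistency_z == pytest.approx(0.0, abs=1e-9)
        shifted = strand_metrics(h, l, _result(0.80, 0.04))
        assert shifted.consistency_z > 2.0


class TestPercentStatistics:
    @pytest.mark.parametrize("observed,expected,value,digits", [
        (6667.0, 6543.0, 1.9, 1),
        (1160.0, 1045.0, 11.0, 1),
        # replicate means are printed rounded, so this recomputes to -12.2
        # rather than the reported -12.3
        (917.0, 1045.0, -12.2, 1),
        (847.0, 1045.0, -19.0, 0),
        (8673.0, 7588.0, 14.0, 0),
        (100.0, 100.0, 0.0, 1),
    ])
    def test_observed_vs_expected(self, observed, expected, value, digits):
        assert round(percent_difference(observed, expected), digits) == value

    def test_zero_expected_rejected(self):
        with pytest.raises(ContractError):
            percent_difference(1.0, 0.0)

    @pytest.mark.parametrize("unsilenced,silenced,value", [
        (136.0, 83.0, 39), (50.0, 50.0, 0), (100.0, 0.0, 100),
    ])
    def test_silencing(self, unsilenced, silenced, value):
        assert round(silencing_percent(unsilenced, silenced)) == value

    def test_silencing_needs_positive_baseline(self):
        with pytest.raises(ContractError):
            silencing_percent(0.0, 10.0)


class TestIntegrations:
    def test_untransduced_control_zero(self):
        integ, total = integrations_per_genome(0.0, 600.0, native_copies=1)
        assert integ.copies_per_genome == 0.0 and total == 1.0

    def test_native_copies_added(self):
        integ, total = integrations_per_genome(28.0 * 600.0, 600.0, native_copies=1)
        assert integ.copies_per_genome == pytest.approx(28.0)
        assert total == pytest.approx(29.0)


class TestReplicateStatistics:
    def test_constant_replicates(self):
        assert aggregate_replicates([2.0, 2.0, 2.0]) == (2.0, 0.0, 3)

    def test_closed_form_sem(self):
        mean, sem, n = aggregate_replicates([1.0, 2.0, 3.0])
        assert (mean, n) == (2.0, 3)
        assert sem == pytest.approx(1.0 / math.sqrt(3))

    def test_single_value_has_no_sem(self):
        assert aggregate_replicates([5.0]) == (5.0, None, 1)

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=8)
        a = aggregate_replicates(vals)
        b = aggregate_replicates(rng.permutation(vals))
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])


class TestGroupComparison:
    def test_identical_constant_groups(self):
        res = compare_groups({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_bonferroni_is_raw_times_pairs_capped(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(loc, 1.0, 6).tolist()
                  for k, loc in [("a", 0.0), ("b", 0.3), ("c", 5.0)]}
        res = compare_groups(groups)
        assert len(res.pairwise) == 3
        for _, _, raw, adj in res.pairwise:
            assert adj == pytest.approx(min(1.0, raw * 3))

    def test_type_one_error_calibrated(self):
        # three null groups, 1000 seeded resamples: ANOVA rejects ~5% at alpha=.05
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(1000):
            groups = {k: rng.normal(0.0, 1.0, 5) for k in "abc"}
            rejections += compare_groups(groups).p_value < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_small_group_rejected(self):
        with pytest.raises(ContractError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
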