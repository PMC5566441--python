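import math

import numpy as np
import pytest

from selfiedpcr import (ClassifiedCounts, DilutionChain, METHODS_CHAIN,
                        confidence_interval, estimate_lambda, merge_wells,
                        qc_flags, to_sample_concentration)
from selfiedpcr.errors import ContractError
from selfiedpcr.quantify import (FLAG_HIGH_SUBSAMPLING_ERROR,
                                 FLAG_NTC_CONTAMINATION, FLAG_SATURATED,
                                 FLAG_TOO_FEW_DROPLETS)


def _counts(positives, total, **kw):
    kw.setdefault("threshold", 5000.0)
    kw.setdefault("method", "manual")
    return ClassifiedCounts(positives=positives, negatives=total - positives, **kw)


class TestEstimateLambda:
    def test_no_positives_gives_zero(self):
        est = estimate_lambda(_counts(0, 20000))
        assert est.lam == 0.0

    def test_half_positive_gives_ln_two(self):
        est = estimate_lambda(_counts(10000, 20000))
        assert est.lam == pytest.approx(math.log(2), abs=1e-9)

    def test_all_positive_saturates(self):
        est = estimate_lambda(_counts(20000, 20000))
        assert est.saturated and math.isinf(est.lam)

    def test_multinomial_partition_recovery(self, rng):
        # independent oracle: throw exactly 5000 molecules into 20000 droplets
        n, molecules = 20000, 5000
        counts = rng.multinomial(molecules, np.full(n, 1.0 / n))
        positives = int(np.count_nonzero(counts))
        est = estimate_lambda(_counts(positives, n))
        recovered = est.lam * n
        se = n * math.sqrt(est.variance)
        assert abs(recovered - molecules) < 3 * se

    @pytest.mark.parametrize("lam", [0.01, 0.1, 1.0, 3.0])
    def test_estimator_relative_bias_small(self, lam, rng):
        # consistency across the dynamic range, 150 partition simulations each
        n = 20000
        molecules = int(round(lam * n))
        rec = []
        for _ in range(150):
            counts = rng.multinomial(molecules, np.full(n, 1.0 / n))
            est = estimate_lambda(_counts(int(np.count_nonzero(counts)), n))
            rec.append(est.lam * n)
        assert abs(np.mean(rec) / molecules - 1) < 0.01


class TestConfidenceInterval:
    def test_zero_positives_lower_bound_zero(self):
        est = estimate_lambda(_counts(0, 20000))
        lo, hi = confidence_interval(est)
        assert lo == 0.0 and hi > 0.0

    def test_more_droplets_narrow_interval(self):
        lo1, hi1 = confidence_interval(estimate_lambda(_counts(2000, 20000)))
        lo2, hi2 = confidence_interval(estimate_lambda(_counts(8000, 80000)))
        assert hi2 - lo2 < hi1 - lo1

    def test_interval_brackets_point_estimate(self):
        for pos, total in [(5, 15000), (100, 20000), (19000, 20000)]:
            est = estimate_lambda(_counts(pos, total))
            lo, hi = confidence_interval(est)
            assert lo <= est.lam <= hi

    def test_coverage_near_nominal(self, rng):
        # quick check at lambda=1; the full 2000-well audit runs in acceptance
        lam, n, hits, trials = 1.0, 20000, 0, 400
        for _ in range(trials):
            neg = rng.binomial(n, math.exp(-lam))
            est = estimate_lambda(_counts(n - neg, n))
            lo, hi = confidence_interval(est)
            hits += lo <= lam <= hi
        assert 0.91 <= hits / trials <= 0.99

    def test_bad_level_rejected(self):
        with pytest.raises(ContractError):
            confidence_interval(estimate_lambda(_counts(10, 100)), level=1.5)


class TestSampleConcentration:
    def test_arithmetic_back_calculation(self):
        est = estimate_lambda(_counts(0, 20000))
        est = type(est)(lam=0.1, variance=1e-6, positives=1906,
                        negatives=18094, total=20000)
        conc = to_sample_concentration(est, METHODS_CHAIN)
        assert conc.copies_per_ul_sample == pytest.approx(0.1 * 20000 / 0.05)

    def test_zero_lambda_zero_concentration(self):
        conc = to_sample_concentration(estimate_lambda(_counts(0, 20000)),
                                       METHODS_CHAIN)
        assert conc.copies_per_ul_sample == 0.0
        assert conc.ci_low == 0.0 and conc.ci_high > 0.0

    def test_dilution_scale_equivariance(self):
        est = estimate_lambda(_counts(1000, 20000))
        base = to_sample_concentration(est, METHODS_CHAIN)
        doubled = DilutionChain(METHODS_CHAIN.sample_input_volume,
                                METHODS_CHAIN.steps + ((1.0, 2.0),),
                                METHODS_CHAIN.reaction_volume)
        conc2 = to_sample_concentration(est, doubled)
        assert conc2.copies_per_ul_sample == pytest.approx(
            2 * base.copies_per_ul_sample)
        assert conc2.ci_high == pytest.approx(2 * base.ci_high)

    def test_ci_brackets_concentration(self):
        est = estimate_lambda(_counts(4, 15000))
        conc = to_sample_concentration(est, METHODS_CHAIN)
        assert conc.ci_low <= conc.copies_per_ul_sample <= conc.ci_high


class TestQCFlags:
    def test_dynamic_range_ceiling(self):
        # 134 negatives of 20000 -> lambda 5.005 -> ~100k copies/reaction
        over = to_sample_concentration(
            estimate_lambda(_counts(20000 - 134, 20000)), METHODS_CHAIN)
        assert FLAG_SATURATED in qc_flags(over)
        under = to_sample_concentration(
            estimate_lambda(_counts(20000 - 150, 20000)), METHODS_CHAIN)
        assert FLAG_SATURATED not in qc_flags(under)

    def test_saturated_when_no_negatives(self):
        conc = to_sample_concentration(
            estimate_lambda(_counts(20000, 20000)), METHODS_CHAIN)
        assert FLAG_SATURATED in qc_flags(conc)

    def test_clean_ntc_not_flagged(self):
        conc = to_sample_concentration(
            estimate_lambda(_counts(1000, 20000)), METHODS_CHAIN)
        flags = qc_flags(conc, ntc_counts=_counts(0, 20000))
        assert FLAG_NTC_CONTAMINATION not in flags

    def test_contaminated_ntc_flagged(self):
        conc = to_sample_concentration(
            estimate_lambda(_counts(1000, 20000)), METHODS_CHAIN)
        flags = qc_flags(conc, ntc_counts=_counts(12, 20000))
        assert FLAG_NTC_CONTAMINATION in flags

    def test_sparse_well_flags_subsampling_and_droplet_floor(self):
        conc = to_sample_concentration(
            estimate_lambda(_counts(4, 9000)), METHODS_CHAIN)
        flags = qc_flags(conc)
        assert FLAG_HIGH_SUBSAMPLING_ERROR in flags
        assert FLAG_TOO_FEW_DROPLETS in flags


class TestMergeWells:
    def test_single_well_identity(self):
        c = _counts(100, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        m = merge_wells([c])
        assert (m.positives, m.negatives) == (100, 9900)

    def test_counts_add(self):
        a = _counts(100, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        b = _counts(200, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        m = merge_wells([a, b])
        assert (m.positives, m.total) == (300, 20000)

    def test_mixed_conditions_rejected(self):
        a = _counts(100, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        b = _counts(100, 10000, sample_id="s", target="g", rt_condition="RT_MINUS")
        with pytest.raises(ContractError):
            merge_wells([a, b])

    def test_merge_matches_precision_weighting(self):
        # identical equal-size wells: pooled = weighted combination exactly
        a = _counts(500, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        b = _counts(500, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        pooled = estimate_lambda(merge_wells([a, b]))
        la, lb = estimate_lambda(a), estimate_lambda(b)
        weighted = ((la.lam / la.variance + lb.lam / lb.variance)
                    / (1 / la.variance + 1 / lb.variance))
        assert pooled.lam == pytest.approx(weighted, abs=1e-9)
        # nearly-equal counts: agreement to first order
        c = _counts(520, 10000, sample_id="s", target="g", rt_condition="RT_PLUS")
        pooled2 = estimate_lambda(merge_wells([a, c]))
        lc = estimate_lambda(c)
        weighted2 = ((la.lam / la.variance + lc.lam / lc.variance)
                     / (1 / la.variance + 1 / lc.variance))
        assert pooled2.lam == pytest.approx(weighted2, rel=1e-3)
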