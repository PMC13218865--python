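"""Exact 2x2 statistics: Fisher p, odds ratios, exact CIs, multiple testing."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, nchypergeom_fisher
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from rvburden.burden import (ContingencyTable, PrioritisationCriteria,
                             adjust_multiple, burden_scan, collapse_gene,
                             conditional_mle_or, exact_ci, fisher_exact_p,
                             odds_ratio, odds_ratio_from_af, one_sided_p)
from rvburden.variant_io import VariantClass, apply_qc

from conftest import exact_fisher_oracle


def _random_table(rng, max_margin=30):
    while True:
        a, b = int(rng.integers(0, max_margin)), int(rng.integers(0, max_margin))
        c, d = int(rng.integers(0, max_margin)), int(rng.integers(0, max_margin))
        if a + c > 0 and b + d > 0:
            return ContingencyTable(a, c, b, d)


class TestContingencyTable:
    def test_rejects_negative_and_empty_margins(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(1, 1, 0, 0)

    def test_support_bounds(self):
        t = ContingencyTable(3, 7, 2, 8)
        kmin, kmax = t.support()
        assert kmin == 0 and kmax == 5


class TestFisherExactP:
    def test_symmetric_minimal_table(self):
        assert fisher_exact_p(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_diagonal_table_enumeration(self):
        # margins 5/5, alt total 5: only k=0 and k=5 are as extreme, 2/252
        p = fisher_exact_p(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, abs=1e-15)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_p(ContingencyTable(0, 5, 0, 5)) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            t = _random_table(rng)
            expect = exact_fisher_oracle(t.case_alt, t.case_ref,
                                         t.control_alt, t.control_ref)
            assert fisher_exact_p(t) == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(100):
            t = _random_table(rng, max_margin=200)
            expect = fisher_exact([[t.case_alt, t.case_ref],
                                   [t.control_alt, t.control_ref]])[1]
            assert fisher_exact_p(t) == pytest.approx(expect, rel=1e-10, abs=1e-14)

    def test_doubling_method(self):
        t = ContingencyTable(5, 0, 0, 5)
        assert fisher_exact_p(t, method="doubling") == pytest.approx(2 / 252)
        # doubling is never smaller than the smaller one-sided tail
        t2 = ContingencyTable(7, 3, 2, 8)
        assert fisher_exact_p(t2, method="doubling") >= min(
            one_sided_p(t2, "greater"), one_sided_p(t2, "less"))


class TestOddsRatio:
    def test_conventions(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0
        assert odds_ratio(ContingencyTable(5, 737, 0, 68058)) == math.inf
        assert odds_ratio(ContingencyTable(0, 742, 5, 68053)) == 0.0
        assert math.isnan(odds_ratio(ContingencyTable(0, 742, 0, 68058)))

    def test_sample_cross_product(self):
        t = ContingencyTable(8, 734, 25, 68033)
        assert odds_ratio(t) == pytest.approx((8 * 68033) / (734 * 25))

    def test_from_af_agrees_with_large_an_table(self):
        q = 7.84e-5
        direct = odds_ratio_from_af(8, 742, q)
        an = 10**9
        b = round(q * an)
        table = odds_ratio(ContingencyTable(8, 734, b, an - b))
        assert direct == pytest.approx(table, rel=1e-4)

    def test_from_af_conventions(self):
        assert odds_ratio_from_af(5, 742, 0.0) == math.inf
        assert odds_ratio_from_af(0, 742, 1e-4) == 0.0
        assert math.isnan(odds_ratio_from_af(0, 742, 0.0))

    def test_cmle_matches_scipy(self, rng):
        for _ in range(25):
            t = _random_table(rng, max_margin=40)
            ours = conditional_mle_or(t)
            ref = scipy_odds_ratio([[t.case_alt, t.case_ref],
                                    [t.control_alt, t.control_ref]]).statistic
            if math.isinf(ours) or ours == 0.0 or math.isnan(ours):
                assert math.isinf(ref) or ref == 0.0 or math.isnan(ref)
            else:
                assert ours == pytest.approx(ref, rel=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=st.integers(0, 40), c=st.integers(0, 40),
           b=st.integers(0, 40), d=st.integers(0, 40))
    def test_swap_symmetry(self, a, c, b, d):
        """Exchanging case/control inverts the OR and preserves the p-value."""
        if a + c == 0 or b + d == 0:
            return
        t = ContingencyTable(a, c, b, d)
        s = t.swapped()
        orr = odds_ratio(t)
        if math.isfinite(orr) and orr > 0:
            assert odds_ratio(s) == pytest.approx(1.0 / orr, rel=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert fisher_exact_p(s) == pytest.approx(fisher_exact_p(t), abs=1e-12)

    def test_monotone_in_case_alt(self):
        """More case alt alleles never weakens enrichment evidence."""
        prev_or, prev_p = -math.inf, math.inf
        for a in range(0, 12):
            t = ContingencyTable(a, 30 - a, 5, 95)
            orr = odds_ratio(t)
            p_greater = one_sided_p(t, "greater")
            assert orr >= prev_or
            assert p_greater <= prev_p + 1e-12
            prev_or, prev_p = orr, p_greater


class TestExactCI:
    def test_no_association_contains_one(self):
        lo, hi = exact_ci(ContingencyTable(1, 1, 1, 1))
        assert lo < 1.0 < hi

    def test_zero_control_alt_upper_infinite(self):
        lo, hi = exact_ci(ContingencyTable(5, 737, 0, 68058))
        assert hi == math.inf
        assert 0 < lo < math.inf

    def test_zero_case_alt_lower_zero(self):
        lo, hi = exact_ci(ContingencyTable(0, 742, 5, 68053))
        assert lo == 0.0 and math.isfinite(hi)

    def test_matches_scipy_exact_ci(self, rng):
        for _ in range(20):
            t = _random_table(rng, max_margin=40)
            if t.degenerate():
                continue
            lo, hi = exact_ci(t)
            ref = scipy_odds_ratio([[t.case_alt, t.case_ref],
                                    [t.control_alt, t.control_ref]]
                                   ).confidence_interval()
            if math.isfinite(lo) and lo > 0:
                assert lo == pytest.approx(ref.low, rel=1e-6)
            if math.isfinite(hi):
                assert hi == pytest.approx(ref.high, rel=1e-6)

    def test_small_table_tail_inversion_oracle(self):
        """CI limits solve the noncentral-hypergeometric tail equations."""
        t = ContingencyTable(3, 17, 1, 19)
        lo, hi = exact_ci(t, level=0.95)
        A, B, M = t.case_total, t.control_total, t.alt_total
        # at psi = lo, P(X >= a) = 0.025; at psi = hi, P(X <= a) = 0.025
        sf_lo = nchypergeom_fisher.sf(t.case_alt - 1, A + B, M, A, lo)
        cdf_hi = nchypergeom_fisher.cdf(t.case_alt, A + B, M, A, hi)
        assert sf_lo == pytest.approx(0.025, rel=1e-4)
        assert cdf_hi == pytest.approx(0.025, rel=1e-4)

    def test_degenerate_margins(self):
        with pytest.warns(UserWarning):
            assert exact_ci(ContingencyTable(0, 10, 0, 10)) == (0.0, math.inf)


class TestAdjustMultiple:
    def test_single_p_unchanged(self):
        assert adjust_multiple([0.03], "bonferroni")[0] == pytest.approx(0.03)
        assert adjust_multiple([0.03], "bh")[0] == pytest.approx(0.03)

    def test_bh_step_up_hand_computation(self):
        # ranks 1..3 of [.01,.02,.03]: 3*.01/1=.03, 3*.02/2=.03, .03 -> all .03
        np.testing.assert_allclose(adjust_multiple([0.01, 0.02, 0.03], "bh"),
                                   [0.03, 0.03, 0.03])

    def test_bonferroni_family_of_63(self):
        assert adjust_multiple([0.01], "bonferroni", family_size=63)[0] == (
            pytest.approx(0.63))

    def test_bh_never_below_raw_p(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        q = adjust_multiple(p, "bh", family_size=63)
        assert np.all(q >= p - 1e-15)

    def test_bh_matches_hand_step_up_with_family_padding(self, rng):
        p = np.sort(rng.uniform(1e-6, 1, size=10))
        m = 63
        hand = np.minimum.accumulate(
            np.concatenate([(m * p / np.arange(1, 11))[::-1], [np.inf]])[:-1]
        )[::-1]
        hand = np.minimum(hand, 1.0)
        np.testing.assert_allclose(adjust_multiple(p, "bh", family_size=m),
                                   hand, rtol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            adjust_multiple([], "bh")
        with pytest.raises(ValueError):
            adjust_multiple([0.0], "bh")
        with pytest.raises(ValueError):
            adjust_multiple([0.1, 0.2], "bh", family_size=1)


class TestCollapseAndScan:
    def test_collapse_matches_per_variant_sum(self, small_study):
        """Gene AC equals the sum of per-variant alt-allele counts."""
        cohort = apply_qc(small_study.cohort)
        for gene in {g.name for g in small_study.config.genes}:
            ac, case_an, idx = collapse_gene(
                cohort, gene, {VariantClass.MISSENSE, VariantClass.LOF})
            per_variant = cohort.allele_counts()
            assert ac == sum(int(per_variant[i]) for i in idx)
            assert case_an == 2 * cohort.n_individuals

    def test_collapse_reported_maf_precision(self):
        # aggregate MAF as printed: 8/742 -> 0.011, 7/742 -> 0.009
        assert round(8 / 742, 3) == 0.011
        assert round(7 / 742, 3) == 0.009

    def test_scan_results_shape_and_flags(self, small_study):
        cohort = apply_qc(small_study.cohort)
        genes = [g.name for g in small_study.config.genes]
        results = burden_scan(cohort, small_study.panel, genes,
                              default_an=small_study.config.panel_an,
                              compute_ci=False)
        assert len(results) == len(genes) * 2  # missense_lof + synonymous
        for r in results:
            for pb in r.panels.values():
                assert pb.q_fdr >= pb.p_value - 1e-15
                assert pb.p_bonferroni >= pb.p_value - 1e-15
            assert 0.0 <= r.case_maf <= 1.0

    def test_enriched_gene_flagged_significant(self, small_study):
        cohort = apply_qc(small_study.cohort)
        genes = [g.name for g in small_study.config.genes]
        results = burden_scan(cohort, small_study.panel, genes,
                              default_an=small_study.config.panel_an,
                              compute_ci=False)
        sig = {r.gene for r in results
               if r.significant and r.variant_class == "missense_lof"}
        assert "G03" in sig  # the lambda=8 planted gene

    def test_empty_gene_yields_null_result(self, small_study):
        cohort = apply_qc(small_study.cohort)
        results = burden_scan(cohort, small_study.panel, ["ABSENT_GENE"],
                              default_an=small_study.config.panel_an,
                              compute_ci=False)
        for r in results:
            assert r.ac == 0 and r.n_variants == 0 and not r.significant

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            PrioritisationCriteria(or_min=0)
        with pytest.raises(ValueError):
            PrioritisationCriteria(fdr_max=0)
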