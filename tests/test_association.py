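"""Single-SNP statistics against hand computations and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import candigene as cg
from candigene.association import expected_counts_2x2


class TestHwe:
    def test_exact_hwe_counts_give_zero(self):
        res = cg.hwe_chi_square(cg.GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.maf == 0.5

    def test_all_homozygote_extreme_equals_n(self):
        # (50, 0, 50): observed het 0 vs expected n/2 -> chi2 = n
        res = cg.hwe_chi_square(cg.GenotypeCounts(50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)

    def test_monomorphic_is_trivially_in_hwe(self):
        res = cg.hwe_chi_square(cg.GenotypeCounts(40, 0, 0))
        assert (res.chi2, res.p, res.maf) == (0.0, 1.0, 0.0)
        assert res.in_hwe

    def test_brute_force_expected_counts_oracle(self):
        """chi2 equals the definitional sum over a sweep of all triples n<=50."""
        for n0 in range(0, 51, 2):
            for n1 in range(0, 51 - n0, 3):
                for n2 in range(0, 51 - n0 - n1, 2):
                    if n0 + n1 + n2 == 0:
                        continue
                    n = n0 + n1 + n2
                    q = (2 * n2 + n1) / (2 * n)
                    p = 1 - q
                    if q == 0 or p == 0:
                        continue
                    exp = [n * p * p, 2 * n * p * q, n * q * q]
                    chi2 = sum(
                        (o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp)
                    )
                    res = cg.hwe_chi_square(cg.GenotypeCounts(n0, n1, n2))
                    assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_exact_test_matches_chi_square_at_large_counts(self):
        approx = cg.hwe_chi_square(cg.GenotypeCounts(4000, 1800, 230))
        exact = cg.hwe_exact(cg.GenotypeCounts(4000, 1800, 230))
        assert exact.p == pytest.approx(approx.p, abs=0.02)


class TestOddsRatio:
    def test_unit_table_symmetric_about_one(self):
        est = cg.odds_ratio_woolf([[1, 1], [1, 1]])
        assert est.oddsratio == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_correction(self):
        est = cg.odds_ratio_woolf([[5, 0], [10, 3]])
        assert est.continuity_corrected
        assert est.oddsratio == pytest.approx((5.5 * 3.5) / (0.5 * 10.5))

    def test_zero_margin_is_na(self):
        est = cg.odds_ratio_woolf([[0, 0], [10, 5]])
        assert math.isnan(est.oddsratio)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_transposed_comparison_is_reciprocal(self, cells):
        a, b, c, d = cells
        est = cg.odds_ratio_woolf([[a, b], [c, d]])
        flipped = cg.odds_ratio_woolf([[c, d], [a, b]])
        assert flipped.oddsratio == pytest.approx(1 / est.oddsratio)
        assert flipped.ci_low == pytest.approx(1 / est.ci_high)
        assert flipped.ci_high == pytest.approx(1 / est.ci_low)


class TestContingencyTests:
    def test_independent_table_gives_zero(self):
        res = cg.pearson_chi2_2x2([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_chi2_scales_linearly_with_counts(self):
        t = [[20, 10], [8, 16]]
        doubled = [[40, 20], [16, 32]]
        assert cg.pearson_chi2_2x2(doubled).statistic == pytest.approx(
            2 * cg.pearson_chi2_2x2(t).statistic
        )

    def test_fisher_degenerate_margin(self):
        assert cg.fisher_exact_2x2([[0, 0], [12, 9]]).p == 1.0

    def test_fisher_matches_exhaustive_enumeration(self):
        """Two-sided p agrees with brute-force fixed-margin enumeration."""
        rng = np.random.default_rng(0)
        tables = [tuple(rng.integers(0, 11, 4)) for _ in range(200)]
        tables += [(6, 114, 0, 87), (1, 9, 11, 3), (0, 5, 5, 0)]
        for a, b, c, d in tables:
            n = a + b + c + d
            if n == 0 or n > 300:
                continue
            r1, c1 = a + b, a + c
            if r1 in (0, n) or c1 in (0, n):
                continue
            probs = {}
            for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
                probs[x] = (
                    math.comb(r1, x)
                    * math.comb(n - r1, c1 - x)
                    / math.comb(n, c1)
                )
            expected = sum(
                p for p in probs.values() if p <= probs[a] * (1 + 1e-7)
            )
            ours = cg.fisher_exact_2x2([[a, b], [c, d]]).p
            assert ours == pytest.approx(min(1.0, expected), abs=1e-9)
            # and against the scipy reference implementation
            assert ours == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-9
            )

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(40, 400)] * 4))
    def test_pearson_and_fisher_agree_for_large_expected(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        if expected_counts_2x2(table).min() < 20:
            return
        pearson = cg.pearson_chi2_2x2(table).p
        # mid-range, the two-sided Fisher sum differs from chi-square by up
        # to the mode's probability mass (~0.05 even at expected counts of
        # 100+); tight agreement holds in the decision-relevant tail
        if pearson > 0.1:
            return
        assert pearson == pytest.approx(cg.fisher_exact_2x2(table).p, abs=0.02)

    def test_auto_rule_switches_to_fisher(self):
        small = [[2, 8], [1, 9]]
        assert cg.auto_test_2x2(small).method == "fisher_exact"
        large = [[50, 60], [55, 45]]
        assert cg.auto_test_2x2(large).method == "pearson_chi2"


class TestGenotypicModels:
    def test_identical_distributions_give_unit_or(self):
        g = cg.GenotypeCounts(30, 20, 10)
        for model in ("genotype-pairwise", "dominant", "recessive"):
            for row in cg.genotypic_association(g, g, model=model):
                assert row.or_estimate.oddsratio == pytest.approx(1.0)

    def test_monomorphic_contrast_reported_as_na(self):
        case = cg.GenotypeCounts(100, 0, 0)
        ctrl = cg.GenotypeCounts(85, 0, 0)
        rows = cg.genotypic_association(case, ctrl)
        assert all(math.isnan(r.or_estimate.oddsratio) for r in rows)
        assert all(r.test is None for r in rows)


class TestPower:
    def test_null_power_equals_alpha(self):
        assert cg.power_two_proportions(0.3, 0.0, 200, 200) == pytest.approx(
            0.05, abs=1e-6
        )

    def test_monotone_in_n_and_delta(self):
        p1 = cg.power_two_proportions(0.2, 0.1, 100, 100)
        assert cg.power_two_proportions(0.2, 0.1, 300, 300) > p1
        assert cg.power_two_proportions(0.2, 0.2, 100, 100) > p1

    def test_matches_monte_carlo_rejection_rate(self):
        """Analytic power within 0.02 of simulated chi-square rejections."""
        n1, n2, p, delta = 190, 240, 0.2, 0.2
        analytic = cg.power_two_proportions(p, delta, n1, n2)
        rng = np.random.default_rng(11)
        rej = 0
        reps = 4000
        for _ in range(reps):
            x1 = rng.binomial(n1, p)
            x2 = rng.binomial(n2, p + delta)
            t = [[x1, n1 - x1], [x2, n2 - x2]]
            if cg.pearson_chi2_2x2(t).p < 0.05:
                rej += 1
        assert analytic == pytest.approx(rej / reps, abs=0.02)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            cg.power_two_proportions(0.9, 0.2, 100, 100)


def test_pooled_maf_from_allele_counts():
    cases = cg.AlleleCounts(168, 46, "case")
    controls = cg.AlleleCounts(138, 30, "control")
    assert cg.pooled_maf(cases, controls) == pytest.approx(76 / 382)
    sym = cg.AlleleCounts(50, 50)
    assert cg.pooled_maf(sym, sym) == 0.5
    with pytest.raises(ValueError):
        cg.pooled_maf(cg.AlleleCounts(0, 0), cg.AlleleCounts(0, 0))
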