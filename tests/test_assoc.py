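"""Association statistics, checked against hand arithmetic, independent
formula implementations, statsmodels, and an arbitrary-precision tail
oracle."""

import math

import numpy as np
import pytest
from scipy import stats

from pedlink.assoc import (armitage_trend, association_report, chi2_2x2,
                           collapse, hwe_chi2, logistic_additive_or, maf,
                           neglog10_sf_chi2_1df, odds_ratio, par,
                           power_rare_variant)
from pedlink.types import GenotypeCountTable, ParInput, TwoByTwo

JAPANESE = GenotypeCountTable("Japanese", 10, 135, 16, 1, 9, 374)
KOREAN = GenotypeCountTable("Korean", 0, 30, 8, 0, 6, 217)
CHINESE = GenotypeCountTable("Chinese", 1, 11, 40, 0, 2, 98)


class TestCollapse:
    def test_allelic_counts_alleles(self):
        assert collapse(JAPANESE, "allelic") == TwoByTwo(155, 167, 11, 757)

    def test_dominant_counts_carriers(self):
        assert collapse(JAPANESE, "dominant") == TwoByTwo(145, 16, 10, 374)

    def test_recessive_counts_homozygotes(self):
        assert collapse(JAPANESE, "recessive") == TwoByTwo(10, 151, 1, 383)

    def test_all_zero_table(self):
        z = GenotypeCountTable("z", 0, 0, 0, 0, 0, 0)
        assert collapse(z, "allelic") == TwoByTwo(0, 0, 0, 0)

    def test_additive_has_no_collapse(self):
        with pytest.raises(ValueError, match="additive"):
            collapse(JAPANESE, "additive")


class TestOddsRatio:
    def test_woolf_interval(self):
        orr, lo, hi, corrected = odds_ratio(TwoByTwo(155, 167, 11, 757))
        assert not corrected
        assert orr == pytest.approx(63.87, abs=0.005)
        assert lo == pytest.approx(33.88, abs=0.005)
        assert hi == pytest.approx(120.42, abs=0.005)

    def test_unit_table_symmetric_in_log_space(self):
        orr, lo, hi, _ = odds_ratio(TwoByTwo(1, 1, 1, 1))
        assert orr == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_zero_cell_gets_haldane_anscombe(self):
        orr, lo, hi, corrected = odds_ratio(TwoByTwo(5, 0, 2, 10))
        assert corrected
        assert orr == pytest.approx(5.5 * 10.5 / (0.5 * 2.5))

    def test_swapping_rows_inverts_or(self):
        t = TwoByTwo(7, 11, 13, 17)
        o1 = odds_ratio(t)[0]
        o2 = odds_ratio(TwoByTwo(13, 17, 7, 11))[0]
        assert o1 * o2 == pytest.approx(1.0)


class TestChi2:
    def test_japanese_allelic_tail(self):
        chi2, nlp = chi2_2x2(TwoByTwo(155, 167, 11, 757))
        assert nlp == pytest.approx(84.63, abs=0.005)

    def test_korean_allelic_tail(self):
        chi2, nlp = chi2_2x2(TwoByTwo(30, 46, 6, 440))
        assert nlp == pytest.approx(33.11, abs=0.005)

    def test_no_association_is_zero(self):
        chi2, nlp = chi2_2x2(TwoByTwo(10, 10, 10, 10))
        assert chi2 == 0.0 and nlp == 0.0

    def test_degenerate_margin_is_zero(self):
        assert chi2_2x2(TwoByTwo(0, 0, 5, 7)) == (0.0, 0.0)

    def test_transposition_invariance(self):
        t = TwoByTwo(12, 5, 9, 31)
        assert chi2_2x2(t)[0] == pytest.approx(
            chi2_2x2(TwoByTwo(12, 9, 5, 31))[0])

    def test_tail_matches_arbitrary_precision_oracle(self):
        import mpmath
        mpmath.mp.dps = 60
        for x in np.linspace(0.001, 700, 60):
            ref = float(-mpmath.log10(
                mpmath.erfc(mpmath.sqrt(mpmath.mpf(float(x)) / 2))))
            assert neglog10_sf_chi2_1df(float(x)) == \
                pytest.approx(ref, abs=0.01)

    def test_tail_agrees_with_scipy_where_scipy_can(self):
        for x in (0.5, 3.84, 10.0, 50.0):
            assert neglog10_sf_chi2_1df(x) == pytest.approx(
                -math.log10(stats.chi2.sf(x, 1)), rel=1e-9)


class TestHWE:
    def test_chinese_cases(self):
        assert hwe_chi2(1, 11, 40) == pytest.approx(0.81, abs=0.005)

    def test_korean_controls(self):
        assert hwe_chi2(0, 6, 217) == pytest.approx(0.84, abs=0.005)

    def test_exact_hwe_counts_give_p_one(self):
        assert hwe_chi2(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_sample_gives_p_one(self):
        assert hwe_chi2(0, 0, 100) == 1.0

    def test_uniform_under_null(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(2000):
            g = rng.multinomial(200, [0.09, 0.42, 0.49])
            ps.append(hwe_chi2(*g))
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestMaf:
    def test_japanese_maf(self):
        assert maf(10, 135, 16) == pytest.approx(155 / 322)
        assert round(maf(10, 135, 16), 2) == 0.48
        assert round(maf(1, 9, 374), 2) == 0.01

    def test_boundary_frequencies(self):
        assert maf(0, 0, 50) == 0.0
        assert maf(50, 0, 0) == 1.0


class TestTrendAndLogistic:
    @staticmethod
    def _trend_oracle(t: GenotypeCountTable) -> float:
        # trend chi2 equals N times the squared dose-status correlation
        dose = np.repeat([0, 1, 2], [t.case_dd + t.control_dd,
                                     t.case_Dd + t.control_Dd,
                                     t.case_DD + t.control_DD])
        y = np.concatenate([
            np.repeat([0, 1], [t.control_dd, t.case_dd]),
            np.repeat([0, 1], [t.control_Dd, t.case_Dd]),
            np.repeat([0, 1], [t.control_DD, t.case_DD])])
        r = np.corrcoef(dose, y)[0, 1]
        return len(y) * r * r

    @pytest.mark.parametrize("table", [
        JAPANESE, CHINESE,
        GenotypeCountTable("gradient", 90, 10, 0, 0, 10, 90),
        GenotypeCountTable("mild", 3, 20, 77, 1, 12, 87),
    ])
    def test_trend_matches_correlation_identity(self, table):
        assert armitage_trend(table)[0] == pytest.approx(
            self._trend_oracle(table), rel=1e-9)

    def test_trend_lies_between_allelic_and_dominant_for_dominant_effect(self):
        x_allelic = chi2_2x2(collapse(JAPANESE, "allelic"))[0]
        x_dominant = chi2_2x2(collapse(JAPANESE, "dominant"))[0]
        x_trend = armitage_trend(JAPANESE)[0]
        assert x_allelic < x_trend < x_dominant

    def test_no_association_trend_is_zero(self):
        t = GenotypeCountTable("null", 4, 32, 64, 4, 32, 64)
        assert armitage_trend(t) == (0.0, 0.0)

    def test_logistic_matches_statsmodels(self):
        import statsmodels.api as sm
        fit = logistic_additive_or(JAPANESE)
        dose = np.array([0.0, 1, 2, 0, 1, 2])
        y = np.array([1, 1, 1, 0, 0, 0])
        w = np.array([JAPANESE.case_dd, JAPANESE.case_Dd, JAPANESE.case_DD,
                      JAPANESE.control_dd, JAPANESE.control_Dd,
                      JAPANESE.control_DD])
        res = sm.GLM(y, sm.add_constant(dose),
                     family=sm.families.Binomial(),
                     freq_weights=w).fit()
        assert fit.or_per_allele == pytest.approx(
            math.exp(res.params[1]), rel=1e-8)
        wald_se = math.log(fit.ci_high / fit.or_per_allele) / 1.959963984540054
        assert wald_se == pytest.approx(res.bse[1], rel=1e-6)

    def test_logistic_null_scenario_estimates_one(self):
        t = GenotypeCountTable("null", 40, 320, 640, 20, 160, 320)
        fit = logistic_additive_or(t)
        assert fit.or_per_allele == pytest.approx(1.0, abs=1e-8)
        assert not fit.corrected

    def test_logistic_separation_flagged_and_corrected(self):
        t = GenotypeCountTable("sep", 50, 0, 0, 0, 0, 50)
        fit = logistic_additive_or(t)
        assert fit.corrected

    def test_logistic_coverage_of_planted_per_allele_or(self):
        rng = np.random.default_rng(20)
        beta = math.log(3.0)
        p = 0.2
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])  # dd,Dd,DD
        case_probs = hwe * np.exp(beta * np.arange(3))
        case_probs /= case_probs.sum()
        hits = 0
        for _ in range(100):
            ctl = rng.multinomial(1000, hwe)
            cas = rng.multinomial(1000, case_probs)
            t = GenotypeCountTable("sim", int(cas[2]), int(cas[1]),
                                   int(cas[0]), int(ctl[2]), int(ctl[1]),
                                   int(ctl[0]))
            fit = logistic_additive_or(t)
            hits += fit.ci_low <= 3.0 <= fit.ci_high
        assert hits >= 90


class TestParAndPower:
    @pytest.mark.parametrize("K,carriers,expected", [
        (161, 145, 90), (38, 30, 79), (52, 12, 23)])
    def test_par_from_carrier_counts(self, K, carriers, expected):
        assert round(par(ParInput(K, K - carriers))) == expected

    def test_par_edge_cases(self):
        assert par(ParInput(10, 10)) == 0.0
        with pytest.raises(ValueError):
            par(ParInput(0, 0))

    def test_power_closed_form(self):
        assert power_rare_variant(70, 0.02) == pytest.approx(
            1 - 0.98 ** 70)
        assert round(power_rare_variant(70, 0.02), 3) == 0.757
        assert power_rare_variant(70, 0.0) == 0.0
        assert power_rare_variant(70, 1.0) == 1.0


class TestReport:
    def test_pooled_total_row(self):
        report = association_report([JAPANESE, KOREAN, CHINESE])
        assert set(report) == {"Japanese", "Korean", "Chinese", "Total"}
        total = JAPANESE.pooled_with(KOREAN).pooled_with(CHINESE)
        assert (total.case_DD, total.case_Dd, total.case_dd) == (11, 176, 64)
        assert (total.control_DD, total.control_Dd,
                total.control_dd) == (1, 17, 689)
        pooled_dom = report["Total"]["dominant"]
        direct = odds_ratio(TwoByTwo(187, 64, 18, 689))[0]
        assert pooled_dom.odds_ratio == pytest.approx(direct)

    def test_single_stratum_has_no_total(self):
        report = association_report([JAPANESE], models=("allelic",))
        assert list(report) == ["Japanese"]
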