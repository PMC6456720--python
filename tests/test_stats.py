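"""Filtering and regression layer: exact fixtures and textbook closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tempoprep import stats as bst


class TestFilterRts:
    def test_hand_evaluated_fixture(self):
        # median 320, MAD 20, upper cut 380; 90 fails the 100 ms floor,
        # 5000 the MAD cut: 5 of 7 survive
        rts = [90, 300, 310, 320, 330, 340, 5000]
        mask = bst.filter_rts(rts)
        assert mask.tolist() == [False, True, True, True, True, True, False]
        assert mask.sum() == 5

    def test_degenerate_spread_keeps_everything(self):
        assert bst.filter_rts([250] * 6).all()

    def test_everything_below_floor_invalid(self):
        assert not bst.filter_rts([50, 80, 99]).any()

    def test_rule_is_one_sided_above(self):
        # a fast-but-legal response is never cut by the MAD rule
        mask = bst.filter_rts([120, 300, 305, 310, 315])
        assert mask[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bst.filter_rts([])

    @pytest.mark.parametrize("seed", range(10))
    def test_upper_cut_is_monotone(self, seed):
        # the rule is a single pass: anything slower than an invalid-slow
        # response is invalid too, and the mask preserves input order
        rng = np.random.Generator(np.random.PCG64(seed))
        rts = rng.lognormal(np.log(350), 0.3, size=40)
        mask = bst.filter_rts(rts)
        cut = np.median(rts) + 3 * np.median(np.abs(rts - np.median(rts)))
        slow_invalid = rts[(~mask) & (rts >= 100)]
        if slow_invalid.size:
            assert (rts[rts > slow_invalid.min()] > cut).all()


class TestPoissonRegression:
    def test_flat_response_gives_zero_slope(self):
        tp = np.tile([1, 2, 3, 4], 25)
        res = bst.poisson_regression(np.full(100, 350.0), tp)
        assert res.beta1 == pytest.approx(0.0, abs=1e-10)
        assert np.exp(res.beta0) == pytest.approx(350.0)

    def test_monotone_slowing_gives_positive_slope(self):
        tp = np.tile([1, 2, 3, 4], 25)
        rts = 300 + 20 * (4 - tp)  # slower as predictability falls
        res = bst.poisson_regression(rts, tp)
        assert res.beta1 > 0
        assert res.r_squared > 0.9

    def test_recovers_generating_coefficients(self):
        # generative truth: exp-link with beta0 = log 334, beta1 = 0.015
        rng = np.random.Generator(np.random.PCG64(8))
        tp = np.tile([1, 2, 3, 4], 120)
        x = 4 - tp
        mu = np.exp(np.log(334.0) + 0.015 * x)
        rts = rng.poisson(mu).astype(float)
        res = bst.poisson_regression(rts, tp)
        # analytic SEs for a Poisson GLM at this design
        se1 = 1.0 / np.sqrt(np.sum(mu * (x - np.average(x, weights=mu)) ** 2))
        assert res.beta1 == pytest.approx(0.015, abs=3 * se1)
        assert np.exp(res.beta0) == pytest.approx(334.0, rel=0.02)

    def test_needs_two_levels_and_positive_rts(self):
        with pytest.raises(ValueError):
            bst.poisson_regression([300, 310], [2, 2])
        with pytest.raises(ValueError):
            bst.poisson_regression([300, -5], [1, 2])


class TestLinearRegressions:
    def test_foreperiod_slope_exact_line(self):
        fp = np.array([1000.0, 1500.0, 2000.0, 3000.0])
        res = bst.foreperiod_slope(400 - 0.02 * fp, fp)
        assert res.beta1 == pytest.approx(-0.02)
        assert res.beta0 == pytest.approx(400.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_foreperiod_flat(self):
        res = bst.foreperiod_slope([350.0] * 4, [1000, 1500, 2000, 2500])
        assert res.beta1 == pytest.approx(0.0)

    def test_boundary_regression_exact_line(self):
        res = bst.boundary_regression([0.9, 0.95, 1.0, 1.05], [4, 3, 2, 1])
        assert res.beta0 == pytest.approx(0.9)
        assert res.beta1 == pytest.approx(0.05)

    def test_boundary_regression_flat_profile(self):
        res = bst.boundary_regression([1.065] * 4, [1, 2, 3, 4])
        assert res.beta0 == pytest.approx(1.065)
        assert res.beta1 == pytest.approx(0.0)

    def test_boundary_regression_names_missing_condition(self):
        with pytest.raises(ValueError, match=r"\[4\]"):
            bst.boundary_regression([0.9, 1.0, 1.1, 1.2], [1, 2, 3, 3])

    def test_condition_relabeling_equivariance(self):
        # shuffling input order while keeping (value, rank) pairs intact
        # cannot change the fitted line
        b = [0.9, 0.95, 1.0, 1.05]
        ranks = [4, 3, 2, 1]
        r1 = bst.boundary_regression(b, ranks)
        r2 = bst.boundary_regression(b[::-1], ranks[::-1])
        assert (r1.beta0, r1.beta1) == pytest.approx((r2.beta0, r2.beta1))


class TestGroupTests:
    def test_identical_groups_null_anova(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = bst.group_tests([g, g, g], "anova")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.effect_label == "eta_squared"
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_paired_dz_matches_hand_computation(self):
        a = np.array([2.0, 4.0, 3.0, 6.0, 5.0])
        b = a - np.array([1.0, 0.5, 1.5, 1.0, 1.0])
        res = bst.group_tests([a, b], "paired_t")
        diff = a - b
        assert res.effect_size == pytest.approx(diff.mean() / diff.std(ddof=1))
        assert res.df == 4

    def test_welch_df_below_pooled_df(self):
        rng = np.random.Generator(np.random.PCG64(3))
        a = rng.normal(0, 1, 16)
        b = rng.normal(0, 10, 16)
        res = bst.group_tests([a, b], "welch_posthoc")
        # Welch-Satterthwaite oracle
        sa, sb = a.var(ddof=1) / 16, b.var(ddof=1) / 16
        df_oracle = (sa + sb) ** 2 / (sa**2 / 15 + sb**2 / 15)
        assert res.df == pytest.approx(df_oracle)
        assert res.df < 30

    def test_one_sample_one_sided(self):
        x = np.array([0.5, 0.7, 0.4, 0.6, 0.65, 0.55])
        res = bst.group_tests(x, "one_sample_t", alternative="greater")
        oracle = sps.ttest_1samp(x, 0.0, alternative="greater")
        assert res.p == pytest.approx(oracle.pvalue)
        assert res.p < 0.01

    def test_misaligned_pairing_rejected(self):
        with pytest.raises(ValueError):
            bst.group_tests([np.ones(4), np.ones(5)], "paired_t")


class TestCorrelationTools:
    def test_spearman_monotone_limits(self):
        assert bst.spearman_boundary_rt([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert bst.spearman_boundary_rt([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_fisher_z_closed_form(self):
        assert bst.fisher_z(0.0) == 0.0
        assert bst.fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert bst.fisher_z(-0.3) == pytest.approx(-bst.fisher_z(0.3))

    def test_fisher_z_rejects_degenerate_r(self):
        with pytest.raises(ValueError):
            bst.fisher_z(1.0)

    def test_bonferroni_threshold_for_three_contrasts(self):
        assert bst.bonferroni_threshold() == pytest.approx(0.05 / 3)
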