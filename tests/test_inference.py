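"""Hierarchical inference: model structure, sampler, diagnostics, overlap."""

import numpy as np
import pytest

from tempoprep import inference as inf
from tempoprep.cohort import GroupTruth, generate_cohort
from tempoprep.stats import apply_rt_filter

from conftest import small_cohort_spec


class TestBuildModel:
    def test_variant_parameterisation(self, small_cohort):
        trials, _ = small_cohort
        m1 = inf.build_model("M1_boundary", trials)
        names = m1.param_names()
        assert sum(1 for n in names if n.startswith("G:mu_b[")) == 4
        assert names.count("G:mu_v") == 1
        m2 = inf.build_model("M2_drift", trials)
        names2 = m2.param_names()
        assert names2.count("G:mu_b") == 1
        assert sum(1 for n in names2 if n.startswith("G:mu_v[")) == 4
        m3 = inf.build_model("M3_both", trials)
        assert sum(1 for n in m3.param_names() if ":mu_b[" in n or ":mu_v[" in n) == 8

    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown model variant"):
            inf.build_model("M4_everything", small_cohort[0])

    def test_empty_cell_named_in_error(self, small_cohort):
        trials, _ = small_cohort
        s0 = trials["subject_id"].iloc[0]
        broken = trials[~((trials["subject_id"] == s0) & (trials["tp_rank"] == 4))]
        with pytest.raises(ValueError, match=s0):
            inf.build_model("M1_boundary", broken)

    def test_single_subject_hierarchy_is_well_defined(self, small_cohort):
        trials, _ = small_cohort
        s0 = trials["subject_id"].iloc[0]
        model = inf.build_model("M1_boundary", trials[trials["subject_id"] == s0])
        fit = inf.fit_mcmc(model, n_samples=300, n_burn=100, n_chains=1, seed=2)
        assert fit.draws.shape[1] == 200


class TestSampler:
    def test_deterministic_given_seed(self, small_cohort):
        trials, _ = small_cohort
        model = inf.build_model("M1_boundary", trials)
        f1 = inf.fit_mcmc(model, n_samples=400, n_burn=100, n_chains=2, seed=9)
        f2 = inf.fit_mcmc(model, n_samples=400, n_burn=100, n_chains=2, seed=9)
        assert np.array_equal(f1.draws, f2.draws)
        f3 = inf.fit_mcmc(model, n_samples=400, n_burn=100, n_chains=2, seed=10)
        assert not np.array_equal(f1.draws, f3.draws)

    def test_null_likelihood_recovers_priors(self, small_cohort):
        """With the data likelihood silenced, the group-mean marginals must
        reproduce the priors (here: drift mean ~ N(2, 3))."""
        trials, _ = small_cohort
        model = inf.build_model("M1_boundary", trials, null_likelihood=True)
        fit = inf.fit_mcmc(model, n_samples=40_000, n_burn=8_000, n_chains=2, seed=4)
        mu_v = fit.pooled("G:mu_v")
        assert abs(mu_v.mean() - 2.0) < 0.5  # prior location 2
        assert 2.0 < mu_v.std() < 4.0  # prior scale 3

    def test_guards(self, small_cohort):
        trials, _ = small_cohort
        model = inf.build_model("M1_boundary", trials)
        with pytest.raises(ValueError):
            inf.fit_mcmc(model, n_samples=100, n_burn=100)
        with pytest.raises(ValueError):
            inf.fit_mcmc(model, n_chains=0)

    def test_recovery_run_converges_and_covers_truth(self, small_fit):
        model, samples, truth = small_fit
        rh = inf.rhat(samples)
        assert max(rh.values()) < 1.2  # short shared run; looser than production
        tw = truth.pivot_table(index="subject_id", columns="parameter", values="value")
        covered = 0
        for c in range(4):
            lo, hi = samples.credible_interval(f"G:mu_b[{c}]")
            covered += lo <= tw[f"b_tp{4 - c}"].mean() <= hi
        assert covered >= 3


class TestRhat:
    def test_identical_chains_give_unity(self):
        rng = np.random.Generator(np.random.PCG64(0))
        one = rng.normal(size=(1, 200, 2))
        s = inf.PosteriorSamples(
            np.concatenate([one, one]), ["a", "b"], 0, np.zeros((2, 200))
        )
        rh = inf.rhat(s)
        assert all(abs(v - 1.0) < 5e-3 for v in rh.values())

    def test_non_mixing_chains_blow_up(self):
        draws = np.stack([np.zeros((100, 1)), np.ones((100, 1))])
        s = inf.PosteriorSamples(draws, ["a"], 0, np.zeros((2, 100)))
        assert inf.rhat(s)["a"] > 1.1  # two chains stuck at different constants

    def test_single_chain_rejected(self):
        s = inf.PosteriorSamples(np.zeros((1, 50, 1)), ["a"], 0, np.zeros((1, 50)))
        with pytest.raises(ValueError, match="two chains"):
            inf.rhat(s)

    def test_agrees_with_arviz_on_mixed_chains(self, small_fit):
        az = pytest.importorskip("arviz")
        _, samples, _ = small_fit
        name = "G:mu_b[0]"
        ours = inf.rhat(samples)[name]
        theirs = float(az.rhat(az.convert_to_dataset(samples.get(name)))["x"])
        assert ours == pytest.approx(theirs, abs=0.05)


class TestDic:
    def test_point_mass_posterior_has_zero_pd(self, small_fit):
        model, samples, _ = small_fit
        mean = samples.posterior_mean()
        point = np.array([mean[n] for n in samples.param_names])
        draws = np.tile(point, (2, 50, 1))
        dev = -2.0 * model.total_loglik(mean)
        s = inf.PosteriorSamples(draws, samples.param_names, 0, np.full((2, 50), dev))
        d, p_d = inf.dic(s, model)
        assert p_d == pytest.approx(0.0, abs=1e-6)
        assert d == pytest.approx(dev, rel=1e-9)

    def test_effective_parameters_positive_for_real_fit(self, small_fit):
        model, samples, _ = small_fit
        d, p_d = inf.dic(samples, model)
        # 4 subjects x (4 b + v + t0) = 24 subject-level parameters
        assert 5 < p_d < 60


class TestOverlapQ:
    def test_identical_sets_overlap_fully(self):
        rng = np.random.Generator(np.random.PCG64(5))
        x = rng.normal(size=5000)
        assert inf.overlap_q(x, x) > 0.95

    def test_disjoint_supports_give_zero(self):
        assert inf.overlap_q([1.0, 2.0, 3.0], [10.0, 11.0]) == 0.0

    def test_matches_monte_carlo_oracle_for_shifted_normals(self):
        # oracle: for X~N(0,1), Y~N(3,1), P(X>Y) = Phi(-3/sqrt(2));
        # computed here by direct MC integration independent of overlap_q
        rng = np.random.Generator(np.random.PCG64(6))
        a = rng.normal(0, 1, 100_000)
        b = rng.normal(3, 1, 100_000)
        oracle = 2.0 * np.mean(rng.normal(0, 1, 500_000) > rng.normal(3, 1, 500_000))
        q = inf.overlap_q(a, b, seed=1)
        assert q == pytest.approx(oracle, abs=0.01)

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.Generator(np.random.PCG64(7))
        a = rng.normal(0, 1, 20_000)
        b = rng.normal(0.5, 1.2, 20_000)
        q_ab = inf.overlap_q(a, b, seed=3)
        assert q_ab == pytest.approx(inf.overlap_q(b, a, seed=3), abs=0.01)
        assert q_ab == pytest.approx(inf.overlap_q(a + 10, b + 10, seed=3), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inf.overlap_q([], [1.0])


class TestPosteriorPredictive:
    def test_single_replicate_summary(self, small_fit):
        model, samples, _ = small_fit
        ppc = inf.posterior_predictive_check(samples, model, n_sims=1, seed=0)
        assert ppc["G"]["n_sims"] == 1
        assert len(ppc["G"]["observed_rt_quantiles"]) == 4

    def test_self_consistency_bands_cover_observed(self, small_fit):
        model, samples, _ = small_fit
        ppc = inf.posterior_predictive_check(samples, model, n_sims=40, seed=1)["G"]
        lo = np.array(ppc["simulated_rt_quantiles_lo"])
        hi = np.array(ppc["simulated_rt_quantiles_hi"])
        obs = np.array(ppc["observed_rt_quantiles"])
        inside = np.mean((obs >= lo) & (obs <= hi))
        assert inside >= 0.8  # model fitted to its own data reproduces it

    def test_misfit_detected_for_wrong_variant(self, small_cohort):
        # a drift-only model cannot reproduce boundary-generated data:
        # some observed quantile or choice proportion leaves the bands
        trials, _ = small_cohort
        model = inf.build_model("M2_drift", trials)
        fit = inf.fit_mcmc(model, n_samples=1500, n_burn=500, n_chains=2, seed=6)
        ppc = inf.posterior_predictive_check(fit, model, n_sims=40, seed=2)["G"]
        q_out = np.any(
            (np.array(ppc["observed_rt_quantiles"]) < np.array(ppc["simulated_rt_quantiles_lo"]))
            | (np.array(ppc["observed_rt_quantiles"]) > np.array(ppc["simulated_rt_quantiles_hi"]))
        )
        c_out = np.any(
            (np.array(ppc["observed_choice_right"]) < np.array(ppc["simulated_choice_lo"]))
            | (np.array(ppc["observed_choice_right"]) > np.array(ppc["simulated_choice_hi"]))
        )
        assert q_out or c_out


class TestCompareModels:
    def _diag(self, name, dic_val, data_id="d1"):
        return inf.FitDiagnostics(name, dic_val, 10.0, {}, None, data_id)

    def test_argmin_wins(self):
        res = inf.compare_models(
            [self._diag("A", 100.0), self._diag("B", 120.0), self._diag("C", 95.0)]
        )
        assert res["winner"] == "C"
        assert res["ranking"] == ["C", "A", "B"]

    def test_tie_reported(self):
        res = inf.compare_models([self._diag("A", 100.0), self._diag("B", 100.0)])
        assert res["ties"] == [("A", "B")]
        assert res["delta_dic"]["A - B"] == pytest.approx(0.0)

    def test_different_datasets_rejected(self):
        with pytest.raises(ValueError, match="different datasets"):
            inf.compare_models([self._diag("A", 1.0, "d1"), self._diag("B", 2.0, "d2")])
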