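"""Diffusion-process checks: densities, absorption probabilities, simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from tempoprep.ddm import (
    DDMParams,
    loglik_trial,
    loglik_trials,
    simulate_fpt,
    upper_prob,
    wfpt_density,
)


class TestUpperProb:
    def test_symmetric_zero_drift_is_half(self):
        assert upper_prob(DDMParams(b=1.0, v=0.0, z=0.5)) == pytest.approx(0.5)

    def test_strong_drift_limits(self):
        assert upper_prob(DDMParams(b=1.0, v=50.0, z=0.2)) == pytest.approx(1.0, abs=1e-6)
        assert upper_prob(DDMParams(b=1.0, v=-50.0, z=0.8)) == pytest.approx(0.0, abs=1e-6)

    def test_continuous_at_zero_drift(self):
        p_eps = upper_prob(DDMParams(b=1.3, v=1e-8, z=0.4))
        assert p_eps == pytest.approx(0.4 / 1.3, rel=1e-5)

    def test_matches_simulation_within_three_mc_ses(self):
        params = DDMParams(b=2.0, v=1.0, z=1.0)
        n = 20_000
        samples = simulate_fpt(params, 42, n=n, dt=1e-3)
        frac = np.mean([s.boundary_hit == "upper" for s in samples])
        p = upper_prob(params)
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / n) + 2e-3  # + small dt bias


class TestSimulator:
    def test_zero_drift_mean_decision_time(self):
        # closed form for driftless absorption: E[T] = z (b - z)
        params = DDMParams(b=1.0, v=0.0, z=0.5)
        samples = simulate_fpt(params, 7, n=20_000, dt=1e-3)
        dts = np.array([s.decision_time for s in samples])
        se = dts.std() / math.sqrt(dts.size)
        assert abs(dts.mean() - 0.25) < 3 * se + 1e-3

    def test_rt_includes_non_decision_time(self):
        params = DDMParams(b=1.0, v=2.0, z=0.5, t0=0.3)
        s = simulate_fpt(params, 1, dt=1e-3)
        assert s.rt == pytest.approx(s.decision_time + 0.3)
        assert s.rt > 0.3

    def test_censoring_flagged_not_dropped(self):
        # huge boundary, tiny cap: every walk is censored but still returned
        params = DDMParams(b=50.0, v=0.0, z=25.0)
        samples = simulate_fpt(params, 3, n=10, dt=1e-3, t_max=0.05)
        assert len(samples) == 10
        assert all(s.censored for s in samples)

    def test_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError):
            simulate_fpt(DDMParams(1, 1, 0.5), 1, dt=0.0)


STRESS = [
    (0.5, -3.0, 0.2), (0.5, 0.0, 0.5), (0.5, 3.0, 0.8),
    (1.5, -1.0, 0.3), (1.5, 0.8, 0.5), (1.5, 2.0, 0.7),
    (3.0, -2.0, 0.4), (3.0, 0.5, 0.5), (3.0, 3.0, 0.2),
]


class TestWfptDensity:
    @pytest.mark.parametrize("b,v,wrel", STRESS)
    def test_total_absorption_mass_is_one(self, b, v, wrel):
        params = DDMParams(b=b, v=v, z=wrel * b)
        total = sum(
            quad(lambda t: wfpt_density(t, side, params), 1e-9, 80, limit=400)[0]
            for side in ("lower", "upper")
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_upper_mass_matches_analytic_absorption_probability(self):
        params = DDMParams(b=2.0, v=1.0, z=1.0)
        mass = quad(lambda t: wfpt_density(t, "upper", params), 1e-9, 80, limit=400)[0]
        assert mass == pytest.approx(upper_prob(params), abs=1e-4)

    def test_zero_below_t0_by_contract(self):
        params = DDMParams(b=1.0, v=1.0, z=0.5, t0=0.3)
        assert wfpt_density(0.29, "upper", params) == 0.0
        assert wfpt_density(0.3, "lower", params) == 0.0

    def test_rejects_nonpositive_err_tol(self):
        with pytest.raises(ValueError):
            wfpt_density(0.5, "upper", DDMParams(1, 1, 0.5), err_tol=0.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        b=st.floats(0.5, 3.0),
        v=st.floats(-3.0, 3.0),
        wrel=st.floats(0.2, 0.8),
        t=st.floats(0.05, 3.0),
    )
    def test_reflection_symmetry(self, b, v, wrel, t):
        """density(upper | v, z) == density(lower | -v, b - z) pointwise."""
        up = wfpt_density(t, "upper", DDMParams(b=b, v=v, z=wrel * b))
        lo = wfpt_density(t, "lower", DDMParams(b=b, v=-v, z=(1 - wrel) * b))
        assert up == pytest.approx(lo, rel=1e-9, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(b=st.floats(0.6, 2.5), v=st.floats(-2.0, 2.0), t=st.floats(0.05, 2.0))
    def test_series_expansions_agree_at_tight_tolerance(self, b, v, t):
        """Tightening err_tol must not move the density (the small- and
        large-time expansions agree in their overlap)."""
        params = DDMParams(b=b, v=v, z=0.5 * b)
        loose = wfpt_density(t, "upper", params, err_tol=1e-5)
        tight = wfpt_density(t, "upper", params, err_tol=1e-12)
        assert loose == pytest.approx(tight, rel=1e-4, abs=1e-10)

    def test_density_matches_simulated_distribution(self):
        # Kolmogorov-Smirnov distance between 20k simulated first passages
        # and the numerically integrated density CDF
        params = DDMParams(b=1.5, v=0.8, z=0.75, t0=0.3)
        n = 20_000
        samples = simulate_fpt(params, 11, n=n, dt=2.5e-4)
        rts = np.sort([s.rt for s in samples])
        grid = np.linspace(1e-6, rts.max() - 0.3 + 0.5, 3000)
        pdf = [
            wfpt_density(t + 0.3, "lower", params) + wfpt_density(t + 0.3, "upper", params)
            for t in grid
        ]
        cdf = np.concatenate([[0], np.cumsum(np.diff(grid) * (np.array(pdf[1:]) + pdf[:-1]) / 2)])
        emp = np.arange(1, n + 1) / n
        D = np.max(np.abs(np.interp(rts - 0.3, grid, cdf) - emp))
        assert D < 1.628 / math.sqrt(n)  # KS alpha = 0.01


class TestTrialLoglik:
    def test_impossible_rt_gets_sentinel(self):
        params = DDMParams(b=1.0, v=1.0, z=0.5, t0=0.3)
        assert loglik_trial(0.2, "LEFT", "LEFT", params) == -np.inf

    def test_symmetric_params_make_sides_equivalent(self):
        params = DDMParams(b=1.0, v=0.0, z=0.5, t0=0.1)
        for rt in (0.3, 0.5, 1.0):
            assert loglik_trial(rt, "LEFT", "RIGHT", params) == pytest.approx(
                loglik_trial(rt, "RIGHT", "RIGHT", params)
            )

    def test_stimulus_coding_signs_drift(self):
        # with positive v, a RIGHT response to a RIGHT stimulus (correct) is
        # more likely than a RIGHT response to a LEFT stimulus (error)
        params = DDMParams(b=1.0, v=2.0, z=0.5, t0=0.0)
        assert loglik_trial(0.4, "RIGHT", "RIGHT", params) > loglik_trial(
            0.4, "RIGHT", "LEFT", params
        )

    def test_grid_search_recovers_generating_boundary(self):
        gen = DDMParams(b=1.0, v=3.0, z=0.5, t0=0.25)
        samples = simulate_fpt(gen, 21, n=3000, dt=1e-3)
        rt = np.array([s.rt for s in samples])
        resp_r = np.array([s.boundary_hit == "upper" for s in samples])
        stim_r = np.ones(rt.size, dtype=bool)  # all RIGHT stimuli
        grid = np.arange(0.7, 1.35, 0.05)
        lls = [
            loglik_trials(rt, resp_r, stim_r, DDMParams(b=b, v=3.0, z=0.5 * b, t0=0.25))
            for b in grid
        ]
        assert abs(grid[int(np.argmax(lls))] - 1.0) <= 0.05 + 1e-9
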