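"""Numba-compiled numerical kernels.

Everything here works in the scaled convention used throughout the package:
within-trial diffusion coefficient fixed at 1, time in seconds.  The start
point is expressed as the relative offset ``w = z / b`` from the lower
boundary.  Python-facing wrappers with validation live in :mod:`tempoprep.ddm`
and :mod:`tempoprep.inference`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Wiener first-passage-time density (lower boundary), dual series
# ---------------------------------------------------------------------------


@njit(cache=True)
def wfpt_logpdf_lower(t, v, a, w, err):
    """Log density of absorption at the LOWER boundary at decision time t.

    Drift v > 0 pushes toward the upper boundary; a is the boundary
    separation; w = z/a the relative start point.  Uses the small-time and
    large-time series expansions, switching by the standard truncation-count
    criterion so that the series value of the normalised density is within
    ``err`` of the exact value.
    """
    if t <= 0.0:
        return -np.inf
    tt = t / (a * a)  # normalised time

    # number of terms needed by the large-time expansion
    if np.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(np.pi * tt * err) / (np.pi * np.pi * tt))
        kl = max(kl, 1.0 / (np.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (np.pi * math.sqrt(tt))

    # number of terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * np.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * np.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time expansion is cheaper
        K = int(math.ceil(ks))
        lo = -int(math.floor((K - 1) / 2.0))
        hi = int(math.ceil((K - 1) / 2.0))
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-(wk * wk) / (2.0 * tt))
        p /= math.sqrt(2.0 * np.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k * k) * (np.pi * np.pi) * tt / 2.0) * math.sin(k * np.pi * w)
        p *= np.pi

    if p <= 0.0:
        return -np.inf
    # reattach drift-dependent factor and undo time scaling
    return math.log(p) - v * a * w - (v * v) * t / 2.0 - 2.0 * math.log(a)


@njit(cache=True)
def wfpt_logpdf(t, upper, v, a, w, err):
    """Log density at the named boundary (upper=True/False) at decision time t.

    Uses the reflection identity f_upper(t | v, w) = f_lower(t | -v, 1-w).
    """
    if upper:
        return wfpt_logpdf_lower(t, -v, a, 1.0 - w, err)
    return wfpt_logpdf_lower(t, v, a, w, err)


# ---------------------------------------------------------------------------
# Euler-Maruyama simulator
# ---------------------------------------------------------------------------


@njit(cache=True)
def simulate_fpt_batch(n, b, v, w, dt, t_max, seed):
    """Simulate n first passages of the diffusion dX = v dt + dW from z = w*b.

    Euler-Maruyama stepping with the Brownian-bridge crossing correction:
    when neither endpoint of a step lies outside the boundaries, the walk is
    still declared absorbed with the exact probability that the bridge
    between the endpoints touched a boundary, exp(-2*d0*d1/dt).  This removes
    the O(sqrt(dt)) bias of naive endpoint crossing detection.

    Returns (decision_time, upper_hit, censored); censored walks carry
    decision_time == t_max and are never silently dropped.
    """
    np.random.seed(seed)
    dec = np.empty(n)
    up = np.zeros(n, np.bool_)
    cens = np.zeros(n, np.bool_)
    sq = math.sqrt(dt)
    n_max = int(t_max / dt)
    for i in range(n):
        x = w * b
        absorbed = False
        for step in range(1, n_max + 1):
            x_new = x + v * dt + sq * np.random.normal()
            if x_new >= b:
                up[i] = True
                dec[i] = step * dt
                absorbed = True
                break
            if x_new <= 0.0:
                dec[i] = step * dt
                absorbed = True
                break
            # bridge crossing probabilities for each boundary
            p_up = math.exp(-2.0 * (b - x) * (b - x_new) / dt)
            if np.random.rand() < p_up:
                up[i] = True
                dec[i] = step * dt
                absorbed = True
                break
            p_lo = math.exp(-2.0 * x * x_new / dt)
            if np.random.rand() < p_lo:
                dec[i] = step * dt
                absorbed = True
                break
            x = x_new
        if not absorbed:
            dec[i] = t_max
            cens[i] = True
    return dec, up, cens


@njit(cache=True)
def simulate_trials(b_trial, v_trial, w, t0, dt, t_max, seed):
    """Per-trial simulation with trial-specific boundary and (signed) drift.

    Returns (rt_seconds, upper_hit, censored); rt includes t0.
    """
    np.random.seed(seed)
    n = b_trial.shape[0]
    rt = np.empty(n)
    up = np.zeros(n, np.bool_)
    cens = np.zeros(n, np.bool_)
    sq = math.sqrt(dt)
    n_max = int(t_max / dt)
    for i in range(n):
        b = b_trial[i]
        v = v_trial[i]
        x = w * b
        absorbed = False
        for step in range(1, n_max + 1):
            x_new = x + v * dt + sq * np.random.normal()
            if x_new >= b:
                up[i] = True
                rt[i] = t0 + step * dt
                absorbed = True
                break
            if x_new <= 0.0:
                rt[i] = t0 + step * dt
                absorbed = True
                break
            p_up = math.exp(-2.0 * (b - x) * (b - x_new) / dt)
            if np.random.rand() < p_up:
                up[i] = True
                rt[i] = t0 + step * dt
                absorbed = True
                break
            p_lo = math.exp(-2.0 * x * x_new / dt)
            if np.random.rand() < p_lo:
                rt[i] = t0 + step * dt
                absorbed = True
                break
            x = x_new
        if not absorbed:
            rt[i] = t0 + t_max
            cens[i] = True
    return rt, up, cens


# ---------------------------------------------------------------------------
# Trial-set log likelihood under stimulus coding
# ---------------------------------------------------------------------------


@njit(cache=True)
def loglik_cell(rt, up, stim_right, a, v, t0, w, err):
    """Summed log likelihood of a set of trials sharing one (b, v) pair.

    Stimulus coding: drift is +v when the stimulus is RIGHT, -v when LEFT;
    RIGHT responses are absorptions at the upper boundary.
    """
    total = 0.0
    for i in range(rt.shape[0]):
        t = rt[i] - t0
        if t <= 0.0:
            return -np.inf
        vs = v if stim_right[i] else -v
        ll = wfpt_logpdf(t, up[i], vs, a, w, err)
        if ll == -np.inf:
            return -np.inf
        total += ll
    return total


@njit(cache=True)
def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd)


@njit(cache=True)
def _total_loglik_subject(rt, up, sr, off, s, n_cond, b_row, v_row, t0, w, err):
    """Log likelihood of one subject across all condition cells."""
    tot = 0.0
    for c in range(n_cond):
        i0 = off[s, c]
        i1 = off[s, c + 1]
        a = b_row[c] if b_row.shape[0] > 1 else b_row[0]
        v = v_row[c] if v_row.shape[0] > 1 else v_row[0]
        ll = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, v, t0, w, err)
        if ll == -np.inf:
            return -np.inf
        tot += ll
    return tot


@njit(cache=True)
def mcmc_group(
    rt,
    up,
    sr,
    off,          # (S, n_cond+1) trial offsets, trials sorted by subject then condition
    n_cond,
    cb,           # 4 if boundary condition-varying else 1
    cv,           # 4 if drift condition-varying else 1
    n_iter,
    n_burn,
    seed,
    w,
    err,
    # priors: group-mean (loc, scale) for b, v, t0; half-normal scale for SDs
    pb_loc, pb_scale,
    pv_loc, pv_scale,
    pt_loc, pt_scale,
    psd_scale,
    init_jitter,
):
    """Adaptive Metropolis-within-Gibbs sampler for one group's hierarchy.

    Parameter vector layout (P columns):
      [mu_b (cb), sd_b, mu_v (cv), sd_v, mu_t0, sd_t0,
       b (S*cb, subject-major), v (S*cv), t0 (S)]
    Returns (samples[n_keep, P], deviance[n_keep], accept_rate[P]).
    """
    np.random.seed(seed)
    S = off.shape[0]
    P = cb + 1 + cv + 1 + 2 + S * cb + S * cv + S
    b_min = 1e-3

    # ---- initial state: moderate values jittered per subject
    mu_b = np.empty(cb)
    for c in range(cb):
        mu_b[c] = 1.0 + 0.05 * np.random.normal() * init_jitter
    sd_b = 0.2
    mu_v = np.empty(cv)
    for c in range(cv):
        mu_v[c] = 3.0 + 0.2 * np.random.normal() * init_jitter
    sd_v = 0.5
    # start t0 safely below every subject's fastest response
    mu_t0 = 0.2
    sd_t0 = 0.05
    b = np.empty((S, cb))
    v = np.empty((S, cv))
    t0 = np.empty(S)
    min_rt = np.empty(S)
    for s in range(S):
        mr = 1e30
        for i in range(off[s, 0], off[s, n_cond]):
            if rt[i] < mr:
                mr = rt[i]
        min_rt[s] = mr
        for c in range(cb):
            b[s, c] = mu_b[c] + 0.05 * np.random.normal() * init_jitter
        for c in range(cv):
            v[s, c] = mu_v[c] + 0.2 * np.random.normal() * init_jitter
        t0[s] = min(0.6 * mr, 0.2)

    # cached per-(subject, condition) cell logliks
    ll = np.empty((S, n_cond))
    for s in range(S):
        for c in range(n_cond):
            a = b[s, c] if cb > 1 else b[s, 0]
            vv = v[s, c] if cv > 1 else v[s, 0]
            i0, i1 = off[s, c], off[s, c + 1]
            ll[s, c] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, vv, t0[s], w, err)

    # proposal scales: one per scalar parameter plus one per joint
    # translation move (group mean + all subject values shifted together,
    # which decorrelates the centred hierarchy); adapted during burn-in
    n_shift = cb + cv + 1
    scale = np.empty(P + n_shift)
    n_hyper = cb + 1 + cv + 1 + 2
    for j in range(P + n_shift):
        scale[j] = 0.05
    acc = np.zeros(P + n_shift)
    tries = np.zeros(P + n_shift)

    n_keep = n_iter - n_burn
    samples = np.empty((n_keep, P))
    deviance = np.empty(n_keep)
    gamma = 0.05  # Robbins-Monro-style adaptation gain (burn-in only)
    target = 0.35

    for it in range(n_iter):
        adapting = it < n_burn

        # ---- subject-level boundary parameters
        for s in range(S):
            for c in range(cb):
                j = n_hyper + s * cb + c
                prop = b[s, c] + scale[j] * np.random.normal()
                tries[j] += 1.0
                ok = prop > b_min
                if ok:
                    if cb > 1:
                        i0, i1 = off[s, c], off[s, c + 1]
                        vv = v[s, c] if cv > 1 else v[s, 0]
                        ll_new = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], prop, vv, t0[s], w, err)
                        d_ll = ll_new - ll[s, c]
                    else:
                        ll_new_all = np.empty(n_cond)
                        d_ll = 0.0
                        for cc in range(n_cond):
                            i0, i1 = off[s, cc], off[s, cc + 1]
                            vv = v[s, cc] if cv > 1 else v[s, 0]
                            ll_new_all[cc] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], prop, vv, t0[s], w, err)
                            d_ll += ll_new_all[cc] - ll[s, cc]
                    d_pr = _norm_logpdf(prop, mu_b[c], sd_b) - _norm_logpdf(b[s, c], mu_b[c], sd_b)
                    if d_ll + d_pr > math.log(np.random.rand() + 1e-300):
                        b[s, c] = prop
                        if cb > 1:
                            ll[s, c] = ll_new
                        else:
                            for cc in range(n_cond):
                                ll[s, cc] = ll_new_all[cc]
                        acc[j] += 1.0
                        if adapting:
                            scale[j] *= math.exp(gamma * (1.0 - target))
                    elif adapting:
                        scale[j] *= math.exp(-gamma * target)
                elif adapting:
                    scale[j] *= math.exp(-gamma * target)

        # ---- subject-level drift parameters
        for s in range(S):
            for c in range(cv):
                j = n_hyper + S * cb + s * cv + c
                prop = v[s, c] + scale[j] * np.random.normal()
                tries[j] += 1.0
                if cv > 1:
                    i0, i1 = off[s, c], off[s, c + 1]
                    a = b[s, c] if cb > 1 else b[s, 0]
                    ll_new = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, prop, t0[s], w, err)
                    d_ll = ll_new - ll[s, c]
                else:
                    ll_new_all = np.empty(n_cond)
                    d_ll = 0.0
                    for cc in range(n_cond):
                        i0, i1 = off[s, cc], off[s, cc + 1]
                        a = b[s, cc] if cb > 1 else b[s, 0]
                        ll_new_all[cc] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, prop, t0[s], w, err)
                        d_ll += ll_new_all[cc] - ll[s, cc]
                d_pr = _norm_logpdf(prop, mu_v[c], sd_v) - _norm_logpdf(v[s, c], mu_v[c], sd_v)
                if d_ll + d_pr > math.log(np.random.rand() + 1e-300):
                    v[s, c] = prop
                    if cv > 1:
                        ll[s, c] = ll_new
                    else:
                        for cc in range(n_cond):
                            ll[s, cc] = ll_new_all[cc]
                    acc[j] += 1.0
                    if adapting:
                        scale[j] *= math.exp(gamma * (1.0 - target))
                elif adapting:
                    scale[j] *= math.exp(-gamma * target)

        # ---- subject-level non-decision time
        for s in range(S):
            j = n_hyper + S * cb + S * cv + s
            prop = t0[s] + scale[j] * np.random.normal()
            tries[j] += 1.0
            ok = 0.0 < prop < min_rt[s]
            if ok:
                ll_new_all = np.empty(n_cond)
                d_ll = 0.0
                for cc in range(n_cond):
                    i0, i1 = off[s, cc], off[s, cc + 1]
                    a = b[s, cc] if cb > 1 else b[s, 0]
                    vv = v[s, cc] if cv > 1 else v[s, 0]
                    ll_new_all[cc] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, vv, prop, w, err)
                    d_ll += ll_new_all[cc] - ll[s, cc]
                d_pr = _norm_logpdf(prop, mu_t0, sd_t0) - _norm_logpdf(t0[s], mu_t0, sd_t0)
                if d_ll + d_pr > math.log(np.random.rand() + 1e-300):
                    t0[s] = prop
                    for cc in range(n_cond):
                        ll[s, cc] = ll_new_all[cc]
                    acc[j] += 1.0
                    if adapting:
                        scale[j] *= math.exp(gamma * (1.0 - target))
                elif adapting:
                    scale[j] *= math.exp(-gamma * target)
            elif adapting:
                scale[j] *= math.exp(-gamma * target)

        # ---- group-level means and SDs (Metropolis on subject-value likelihood)
        for c in range(cb):
            j = c
            prop = mu_b[c] + scale[j] * np.random.normal()
            tries[j] += 1.0
            if prop > 0.0:
                d = _norm_logpdf(prop, pb_loc, pb_scale) - _norm_logpdf(mu_b[c], pb_loc, pb_scale)
                for s in range(S):
                    d += _norm_logpdf(b[s, c], prop, sd_b) - _norm_logpdf(b[s, c], mu_b[c], sd_b)
                if d > math.log(np.random.rand() + 1e-300):
                    mu_b[c] = prop
                    acc[j] += 1.0
                    if adapting:
                        scale[j] *= math.exp(gamma * (1.0 - target))
                elif adapting:
                    scale[j] *= math.exp(-gamma * target)
            elif adapting:
                scale[j] *= math.exp(-gamma * target)

        j = cb
        prop = sd_b + scale[j] * np.random.normal()
        tries[j] += 1.0
        if prop > 1e-4:
            d = -0.5 * (prop / psd_scale) ** 2 + 0.5 * (sd_b / psd_scale) ** 2
            for c in range(cb):
                for s in range(S):
                    d += _norm_logpdf(b[s, c], mu_b[c], prop) - _norm_logpdf(b[s, c], mu_b[c], sd_b)
            if d > math.log(np.random.rand() + 1e-300):
                sd_b = prop
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)
        elif adapting:
            scale[j] *= math.exp(-gamma * target)

        for c in range(cv):
            j = cb + 1 + c
            prop = mu_v[c] + scale[j] * np.random.normal()
            tries[j] += 1.0
            d = _norm_logpdf(prop, pv_loc, pv_scale) - _norm_logpdf(mu_v[c], pv_loc, pv_scale)
            for s in range(S):
                d += _norm_logpdf(v[s, c], prop, sd_v) - _norm_logpdf(v[s, c], mu_v[c], sd_v)
            if d > math.log(np.random.rand() + 1e-300):
                mu_v[c] = prop
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)

        j = cb + 1 + cv
        prop = sd_v + scale[j] * np.random.normal()
        tries[j] += 1.0
        if prop > 1e-4:
            d = -0.5 * (prop / psd_scale) ** 2 + 0.5 * (sd_v / psd_scale) ** 2
            for c in range(cv):
                for s in range(S):
                    d += _norm_logpdf(v[s, c], mu_v[c], prop) - _norm_logpdf(v[s, c], mu_v[c], sd_v)
            if d > math.log(np.random.rand() + 1e-300):
                sd_v = prop
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)
        elif adapting:
            scale[j] *= math.exp(-gamma * target)

        j = cb + 1 + cv + 1
        prop = mu_t0 + scale[j] * np.random.normal()
        tries[j] += 1.0
        if prop > 0.0:
            d = _norm_logpdf(prop, pt_loc, pt_scale) - _norm_logpdf(mu_t0, pt_loc, pt_scale)
            for s in range(S):
                d += _norm_logpdf(t0[s], prop, sd_t0) - _norm_logpdf(t0[s], mu_t0, sd_t0)
            if d > math.log(np.random.rand() + 1e-300):
                mu_t0 = prop
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)
        elif adapting:
            scale[j] *= math.exp(-gamma * target)

        j = cb + 1 + cv + 2
        prop = sd_t0 + scale[j] * np.random.normal()
        tries[j] += 1.0
        if prop > 1e-4:
            d = -0.5 * (prop / psd_scale) ** 2 + 0.5 * (sd_t0 / psd_scale) ** 2
            for s in range(S):
                d += _norm_logpdf(t0[s], mu_t0, prop) - _norm_logpdf(t0[s], mu_t0, sd_t0)
            if d > math.log(np.random.rand() + 1e-300):
                sd_t0 = prop
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)
        elif adapting:
            scale[j] *= math.exp(-gamma * target)

        # ---- joint translation moves: shift a group mean and every
        # subject's value by the same delta (subject-level deviations, and
        # hence their prior terms, are unchanged; only the data likelihood
        # and the group-mean prior move)
        for c in range(cb):
            j = P + c
            delta = scale[j] * np.random.normal()
            tries[j] += 1.0
            ok = mu_b[c] + delta > 0.0
            if ok:
                for s in range(S):
                    if b[s, c] + delta <= b_min:
                        ok = False
                        break
            if ok:
                d = _norm_logpdf(mu_b[c] + delta, pb_loc, pb_scale) - _norm_logpdf(mu_b[c], pb_loc, pb_scale)
                ll_new_mat = np.empty((S, n_cond))
                for s in range(S):
                    for cc in range(n_cond):
                        if cb > 1 and cc != c:
                            ll_new_mat[s, cc] = ll[s, cc]
                            continue
                        i0, i1 = off[s, cc], off[s, cc + 1]
                        a = (b[s, c] if cb > 1 else b[s, 0]) + delta
                        vv = v[s, cc] if cv > 1 else v[s, 0]
                        ll_new_mat[s, cc] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, vv, t0[s], w, err)
                        d += ll_new_mat[s, cc] - ll[s, cc]
                if d > math.log(np.random.rand() + 1e-300):
                    mu_b[c] += delta
                    for s in range(S):
                        b[s, c] += delta
                        for cc in range(n_cond):
                            ll[s, cc] = ll_new_mat[s, cc]
                    acc[j] += 1.0
                    if adapting:
                        scale[j] *= math.exp(gamma * (1.0 - target))
                elif adapting:
                    scale[j] *= math.exp(-gamma * target)
            elif adapting:
                scale[j] *= math.exp(-gamma * target)

        for c in range(cv):
            j = P + cb + c
            delta = scale[j] * np.random.normal()
            tries[j] += 1.0
            d = _norm_logpdf(mu_v[c] + delta, pv_loc, pv_scale) - _norm_logpdf(mu_v[c], pv_loc, pv_scale)
            ll_new_mat = np.empty((S, n_cond))
            for s in range(S):
                for cc in range(n_cond):
                    if cv > 1 and cc != c:
                        ll_new_mat[s, cc] = ll[s, cc]
                        continue
                    i0, i1 = off[s, cc], off[s, cc + 1]
                    a = b[s, cc] if cb > 1 else b[s, 0]
                    vv = (v[s, cc] if cv > 1 else v[s, 0]) + delta
                    ll_new_mat[s, cc] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, vv, t0[s], w, err)
                    d += ll_new_mat[s, cc] - ll[s, cc]
            if d > math.log(np.random.rand() + 1e-300):
                mu_v[c] += delta
                for s in range(S):
                    v[s, c] += delta
                    for cc in range(n_cond):
                        ll[s, cc] = ll_new_mat[s, cc]
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)

        j = P + cb + cv
        delta = scale[j] * np.random.normal()
        tries[j] += 1.0
        ok = mu_t0 + delta > 0.0
        if ok:
            for s in range(S):
                t = t0[s] + delta
                if t <= 0.0 or t >= min_rt[s]:
                    ok = False
                    break
        if ok:
            d = _norm_logpdf(mu_t0 + delta, pt_loc, pt_scale) - _norm_logpdf(mu_t0, pt_loc, pt_scale)
            ll_new_mat = np.empty((S, n_cond))
            for s in range(S):
                for cc in range(n_cond):
                    i0, i1 = off[s, cc], off[s, cc + 1]
                    a = b[s, cc] if cb > 1 else b[s, 0]
                    vv = v[s, cc] if cv > 1 else v[s, 0]
                    ll_new_mat[s, cc] = loglik_cell(rt[i0:i1], up[i0:i1], sr[i0:i1], a, vv, t0[s] + delta, w, err)
                    d += ll_new_mat[s, cc] - ll[s, cc]
            if d > math.log(np.random.rand() + 1e-300):
                mu_t0 += delta
                for s in range(S):
                    t0[s] += delta
                    for cc in range(n_cond):
                        ll[s, cc] = ll_new_mat[s, cc]
                acc[j] += 1.0
                if adapting:
                    scale[j] *= math.exp(gamma * (1.0 - target))
            elif adapting:
                scale[j] *= math.exp(-gamma * target)
        elif adapting:
            scale[j] *= math.exp(-gamma * target)

        # ---- record
        if it >= n_burn:
            k = it - n_burn
            p = 0
            for c in range(cb):
                samples[k, p] = mu_b[c]
                p += 1
            samples[k, p] = sd_b
            p += 1
            for c in range(cv):
                samples[k, p] = mu_v[c]
                p += 1
            samples[k, p] = sd_v
            p += 1
            samples[k, p] = mu_t0
            p += 1
            samples[k, p] = sd_t0
            p += 1
            for s in range(S):
                for c in range(cb):
                    samples[k, p] = b[s, c]
                    p += 1
            for s in range(S):
                for c in range(cv):
                    samples[k, p] = v[s, c]
                    p += 1
            for s in range(S):
                samples[k, p] = t0[s]
                p += 1
            tot = 0.0
            for s in range(S):
                for c in range(n_cond):
                    tot += ll[s, c]
            deviance[k] = -2.0 * tot

    rate = np.empty(P)
    for j in range(P):
        rate[j] = acc[j] / tries[j] if tries[j] > 0 else 0.0
    return samples, deviance, rate
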