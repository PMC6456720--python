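"""Hierarchical Bayesian estimation of the drift-diffusion variants.

Three competing model variants differ in which diffusion parameter may vary
across the four temporal-predictability levels:

* ``M1_boundary`` — boundary separation b varies, one drift per group;
* ``M2_drift``    — drift rate v varies, one boundary per group;
* ``M3_both``     — both vary.

Non-decision time never varies across predictability levels, the relative
start point is fixed at z/b = 0.5 (no a-priori response bias), and each
group (Control, PD-on, PD-off) gets a fully independent hierarchy: subject
parameters are drawn from group-level normal distributions whose means and
SDs carry weakly-informative priors.

Sampling is adaptive Metropolis-within-Gibbs (proposal scales tuned toward
~35% acceptance during burn-in only), fully deterministic given the seed.
Model comparison uses the conditional deviance information criterion,
DIC = Dbar + p_D with p_D = Dbar - D(posterior mean), evaluated at the
subject-level parameters.  Group inference uses the posterior-overlap
statistic q = 2 * min(P(a > b), P(a < b)), flagged significant below the
Bonferroni-corrected threshold 0.05 / 3 ~ 0.0167.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import loglik_cell, mcmc_group, simulate_trials
from .stats import bonferroni_threshold

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "PriorSpec",
    "PosteriorSamples",
    "FitDiagnostics",
    "HierarchicalModel",
    "build_model",
    "fit_mcmc",
    "rhat",
    "dic",
    "posterior_predictive_check",
    "overlap_q",
    "compare_models",
]

W_FIXED = 0.5  # relative start point, fixed: no a-priori bias
ERR_TOL = 1e-7  # WFPT series truncation error
PPC_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class ModelVariant:
    name: str
    b_varies: bool
    v_varies: bool

    @property
    def condition_varying(self) -> frozenset:
        out = set()
        if self.b_varies:
            out.add("b")
        if self.v_varies:
            out.add("v")
        return frozenset(out)


VARIANTS = {
    "M1_boundary": ModelVariant("M1_boundary", True, False),
    "M2_drift": ModelVariant("M2_drift", False, True),
    "M3_both": ModelVariant("M3_both", True, True),
}


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative priors for group-level means and SDs.

    Means: positive-support normal for b (loc 1.5, scale 0.75), normal for v
    (2, 3), positive-support normal for t0 (0.3 s, 0.25).  SDs: half-normal
    with scale 0.5.  Wide enough to cover the plausible human two-choice RT
    regime without dominating a 480-trial subject.
    """

    b_loc: float = 1.5
    b_scale: float = 0.75
    v_loc: float = 2.0
    v_scale: float = 3.0
    t0_loc: float = 0.3
    t0_scale: float = 0.25
    sd_scale: float = 0.5


@dataclass
class _GroupData:
    subjects: list
    rt: np.ndarray  # seconds, sorted by (subject, condition)
    up: np.ndarray
    sr: np.ndarray
    off: np.ndarray  # (S, n_cond+1) offsets into the trial arrays
    fp_ms: np.ndarray  # foreperiods, for replicate bookkeeping


@dataclass
class HierarchicalModel:
    variant: ModelVariant
    priors: PriorSpec
    groups: dict[str, _GroupData]
    data_id: str  # fingerprint of the trial data, guards model comparison
    n_cond: int = 4
    null_likelihood: bool = False

    @property
    def cb(self) -> int:
        return self.n_cond if self.variant.b_varies else 1

    @property
    def cv(self) -> int:
        return self.n_cond if self.variant.v_varies else 1

    def param_names(self) -> list[str]:
        names = []
        for g, gd in self.groups.items():
            if self.cb > 1:
                names += [f"{g}:mu_b[{c}]" for c in range(self.cb)]
            else:
                names.append(f"{g}:mu_b")
            names.append(f"{g}:sd_b")
            if self.cv > 1:
                names += [f"{g}:mu_v[{c}]" for c in range(self.cv)]
            else:
                names.append(f"{g}:mu_v")
            names += [f"{g}:sd_v", f"{g}:mu_t0", f"{g}:sd_t0"]
            for s in gd.subjects:
                if self.cb > 1:
                    names += [f"{g}:b[{s},{c}]" for c in range(self.cb)]
                else:
                    names.append(f"{g}:b[{s}]")
            for s in gd.subjects:
                if self.cv > 1:
                    names += [f"{g}:v[{s},{c}]" for c in range(self.cv)]
                else:
                    names.append(f"{g}:v[{s}]")
            names += [f"{g}:t0[{s}]" for s in gd.subjects]
        return names

    def total_loglik(self, point: dict[str, float]) -> float:
        """Total data log likelihood at a named parameter point (used for the
        deviance at the posterior mean)."""
        total = 0.0
        for g, gd in self.groups.items():
            S = len(gd.subjects)
            for si, s in enumerate(gd.subjects):
                t0 = point[f"{g}:t0[{s}]"]
                for c in range(self.n_cond):
                    a = point[f"{g}:b[{s},{c}]"] if self.cb > 1 else point[f"{g}:b[{s}]"]
                    v = point[f"{g}:v[{s},{c}]"] if self.cv > 1 else point[f"{g}:v[{s}]"]
                    i0, i1 = gd.off[si, c], gd.off[si, c + 1]
                    total += loglik_cell(
                        gd.rt[i0:i1], gd.up[i0:i1], gd.sr[i0:i1], a, v, t0, W_FIXED, ERR_TOL
                    )
        return float(total)


@dataclass
class PosteriorSamples:
    """MCMC draws with chain structure: draws[chain, iteration, parameter]."""

    draws: np.ndarray
    param_names: list[str]
    n_burn: int
    deviance: np.ndarray  # (chain, iteration)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chain, iteration, parameter)")
        if self.draws.shape[1] < 1:
            raise ValueError("need at least one post-burn-in iteration")
        self._index = {n: i for i, n in enumerate(self.param_names)}

    def get(self, name: str) -> np.ndarray:
        return self.draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def posterior_mean(self) -> dict[str, float]:
        means = self.draws.reshape(-1, self.draws.shape[2]).mean(axis=0)
        return dict(zip(self.param_names, means))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        x = self.pooled(name)
        lo = (1.0 - level) / 2.0
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (chain, iter, parameter, value) table for persistence."""
        n_chain, n_iter, n_par = self.draws.shape
        chain = np.repeat(np.arange(n_chain), n_iter * n_par)
        it = np.tile(np.repeat(np.arange(n_iter), n_par), n_chain)
        par = np.tile(np.array(self.param_names, dtype=object), n_chain * n_iter)
        return pd.DataFrame(
            {"chain": chain, "iter": it, "parameter": par, "value": self.draws.reshape(-1)}
        )


@dataclass
class FitDiagnostics:
    variant: str
    dic: float
    p_d: float
    rhat: dict[str, float]
    ppc_summaries: dict | None
    data_id: str
    meta: dict = field(default_factory=dict)


def _prepare_group(sub: pd.DataFrame, n_cond: int) -> _GroupData:
    sub = sub.sort_values(["subject_id", "tp_rank"], kind="mergesort")
    subjects = sorted(sub["subject_id"].unique())
    x = (4 - sub["tp_rank"].to_numpy()).astype(np.int64)  # condition index 0..3
    rt = sub["rt_ms"].to_numpy(dtype=np.float64) / 1000.0
    up = sub["response"].eq("RIGHT").to_numpy()
    sr = sub["stimulus"].eq("RIGHT").to_numpy()
    fp = sub["foreperiod_ms"].to_numpy(dtype=np.float64)
    # re-sort trials subject-major then condition-major and build offsets
    sid = sub["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    order = np.lexsort((x, sid))
    rt, up, sr, x, sid, fp = rt[order], up[order], sr[order], x[order], sid[order], fp[order]
    S = len(subjects)
    off = np.zeros((S, n_cond + 1), dtype=np.int64)
    counts = np.zeros((S, n_cond), dtype=np.int64)
    for s_i, c_i in zip(sid, x):
        counts[s_i, c_i] += 1
    pos = 0
    for s in range(S):
        off[s, 0] = pos
        for c in range(n_cond):
            pos += counts[s, c]
            off[s, c + 1] = pos
    return _GroupData(
        subjects=subjects,
        rt=np.ascontiguousarray(rt),
        up=np.ascontiguousarray(up),
        sr=np.ascontiguousarray(sr),
        off=off,
        fp_ms=fp,
    )


def build_model(
    variant: ModelVariant | str,
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    null_likelihood: bool = False,
) -> HierarchicalModel:
    """Assemble the hierarchical model over the valid trials of a trial table.

    One independent hierarchy per group.  Every (group, condition) cell must
    be non-empty unless ``null_likelihood`` is set (prior-recovery smoke
    runs).
    """
    if isinstance(variant, str):
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}; choose from {sorted(VARIANTS)}")
        variant = VARIANTS[variant]
    priors = priors or PriorSpec()
    valid = trials[trials["valid"]].copy()
    groups: dict[str, _GroupData] = {}
    for g, sub in valid.groupby("group", sort=True):
        gd = _prepare_group(sub, 4)
        if not null_likelihood:
            for si, s in enumerate(gd.subjects):
                for c in range(4):
                    if gd.off[si, c + 1] == gd.off[si, c]:
                        raise ValueError(
                            f"empty cell: group {g}, subject {s}, predictability level x={c}"
                        )
        groups[g] = gd
    if not groups:
        raise ValueError("no valid trials")
    data_id = _fingerprint(valid)
    return HierarchicalModel(
        variant=variant, priors=priors, groups=groups, data_id=data_id,
        null_likelihood=null_likelihood,
    )


def _fingerprint(trials: pd.DataFrame) -> str:
    rt = trials["rt_ms"].to_numpy(dtype=np.float64)
    h = hash((len(trials), float(np.round(rt.sum(), 3)), float(np.round(rt.min(), 3))))
    return f"{h & 0xFFFFFFFF:08x}"


def fit_mcmc(
    model: HierarchicalModel,
    n_samples: int = 4000,
    n_burn: int = 1000,
    n_chains: int = 2,
    seed: int = 0,
) -> PosteriorSamples:
    """Run the adaptive Metropolis-within-Gibbs sampler.

    ``n_samples`` counts total iterations per chain, of which the first
    ``n_burn`` are discarded (the production profile of the emulated study is
    50,000 / 5,000).  Deterministic for a given seed.
    """
    if n_samples <= n_burn:
        raise ValueError("n_samples must exceed n_burn")
    if n_chains < 1:
        raise ValueError("need at least one chain")
    pr = model.priors
    n_keep = n_samples - n_burn
    per_group: dict[str, list] = {g: [] for g in model.groups}
    dev_chains = np.zeros((n_chains, n_keep))
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.generate_state(n_chains * max(len(model.groups), 1)).reshape(
        n_chains, -1
    )
    for chain in range(n_chains):
        for gi, (g, gd) in enumerate(model.groups.items()):
            off = gd.off
            if model.null_likelihood:
                off = np.zeros_like(off)  # every cell empty: posterior == prior
            samples, deviance, _rate = mcmc_group(
                gd.rt, gd.up, gd.sr, off, 4,
                model.cb, model.cv,
                n_samples, n_burn,
                int(chain_seeds[chain, gi] & 0x7FFFFFFF),
                W_FIXED, ERR_TOL,
                pr.b_loc, pr.b_scale, pr.v_loc, pr.v_scale,
                pr.t0_loc, pr.t0_scale, pr.sd_scale,
                1.0,
            )
            per_group[g].append(samples)
            dev_chains[chain] += deviance
    draws = np.concatenate(
        [np.stack(per_group[g], axis=0) for g in model.groups], axis=2
    )
    return PosteriorSamples(
        draws=draws,
        param_names=model.param_names(),
        n_burn=n_burn,
        deviance=dev_chains,
        seed=seed,
        meta={
            "variant": model.variant.name,
            "n_samples": n_samples,
            "n_burn": n_burn,
            "n_chains": n_chains,
            "deviance_focus": "subject-level (conditional DIC)",
        },
    )


def rhat(samples: PosteriorSamples) -> dict[str, float]:
    """Gelman-Rubin potential scale reduction, per parameter.

    Classic between/within-chain variance-ratio form: with m chains of n
    draws, W the mean within-chain variance and B/n the variance of chain
    means, R-hat = sqrt(((n-1)/n + B/(n W)) ).  Requires >= 2 chains.
    """
    m, n, _ = samples.draws.shape
    if m < 2:
        raise ValueError("R-hat requires at least two chains")
    if n < 10:
        raise ValueError("R-hat requires at least 10 post-burn-in iterations")
    out = {}
    for j, name in enumerate(samples.param_names):
        x = samples.draws[:, :, j]
        W = x.var(axis=1, ddof=1).mean()
        B = n * x.mean(axis=1).var(ddof=1)
        if W <= 1e-300:
            out[name] = 1.0 if B <= 1e-300 else float("inf")
            continue
        var_plus = (n - 1) / n * W + B / n
        out[name] = float(np.sqrt(var_plus / W))
    return out


def dic(samples: PosteriorSamples, model: HierarchicalModel) -> tuple[float, float]:
    """Conditional DIC and effective parameter count.

    Dbar is the posterior mean deviance recorded during sampling; D(theta_bar)
    is the deviance at the posterior mean of the subject-level parameters;
    p_D = Dbar - D(theta_bar) and DIC = Dbar + p_D.
    """
    dbar = float(samples.deviance.mean())
    d_at_mean = -2.0 * model.total_loglik(samples.posterior_mean())
    p_d = dbar - d_at_mean
    return dbar + p_d, p_d


def overlap_q(samples_a, samples_b, n_resample: int = 100_000, seed: int = 0) -> float:
    """Posterior-overlap statistic q between two groups' draws of the same
    parameter: q = 2 * min(P(a > b), P(a < b)), estimated by paired resampling
    with replacement.  q near 1 means indistinguishable posteriors, q = 0
    disjoint ones; significance is declared below the Bonferroni threshold
    0.05 / 3 ~ 0.0167.
    """
    a = np.asarray(samples_a, dtype=float).reshape(-1)
    b = np.asarray(samples_b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    rng = np.random.Generator(np.random.PCG64(seed))
    ia = rng.integers(a.size, size=n_resample)
    ib = rng.integers(b.size, size=n_resample)
    gt = float(np.mean(a[ia] > b[ib]))
    lt = float(np.mean(a[ia] < b[ib]))
    return 2.0 * min(gt, lt)


def group_overlap_matrix(
    samples: PosteriorSamples, parameter_suffix: str, seed: int = 0
) -> dict[str, dict]:
    """Pairwise overlap q for one parameter across all fitted groups.

    ``parameter_suffix`` is the name without the group prefix, e.g.
    ``mu_b[0]`` or ``mu_t0``.
    """
    groups = sorted({n.split(":")[0] for n in samples.param_names})
    thr = bonferroni_threshold()
    out = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            q = overlap_q(
                samples.pooled(f"{ga}:{parameter_suffix}"),
                samples.pooled(f"{gb}:{parameter_suffix}"),
                seed=seed,
            )
            out[f"{ga} vs {gb}"] = {"q": q, "significant": bool(q < thr), "threshold": thr}
    return out


def posterior_predictive_check(
    samples: PosteriorSamples,
    model: HierarchicalModel,
    n_sims: int = 500,
    seed: int = 0,
    dt: float = 1e-3,
) -> dict:
    """Observed vs simulated RT quantiles and choice proportions.

    For each of ``n_sims`` posterior draws (evenly thinned across chains), a
    full replicate dataset is simulated with the diffusion simulator and
    summarised per group x predictability level: RT quantiles
    (10/30/50/70/90%) and the proportion of RIGHT responses.  The observed
    summaries are reported with the simulated central 95% bands.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    m, n, _ = samples.draws.shape
    flat_idx = np.linspace(0, m * n - 1, n_sims).astype(int)
    rng = np.random.Generator(np.random.PCG64(seed))
    out: dict = {}
    for g, gd in model.groups.items():
        S = len(gd.subjects)
        obs_q = np.zeros((4, len(PPC_QUANTILES)))
        obs_choice = np.zeros(4)
        sim_q = np.zeros((n_sims, 4, len(PPC_QUANTILES)))
        sim_choice = np.zeros((n_sims, 4))
        cond_slices: list[list[tuple[int, int]]] = [[] for _ in range(4)]
        for si in range(S):
            for c in range(4):
                cond_slices[c].append((gd.off[si, c], gd.off[si, c + 1]))
        for c in range(4):
            rts = np.concatenate([gd.rt[i0:i1] for i0, i1 in cond_slices[c]])
            ups = np.concatenate([gd.up[i0:i1] for i0, i1 in cond_slices[c]])
            obs_q[c] = np.quantile(rts, PPC_QUANTILES)
            obs_choice[c] = ups.mean()
        for k, fi in enumerate(flat_idx):
            chain, it = divmod(int(fi), n)
            point = dict(zip(samples.param_names, samples.draws[chain, it]))
            rep_rt: list[list[np.ndarray]] = [[] for _ in range(4)]
            rep_up: list[list[np.ndarray]] = [[] for _ in range(4)]
            for si, s in enumerate(gd.subjects):
                t0 = point[f"{g}:t0[{s}]"]
                n_sub = gd.off[si, 4] - gd.off[si, 0]
                b_tr = np.empty(n_sub)
                v_tr = np.empty(n_sub)
                cond_of = np.empty(n_sub, dtype=int)
                pos = 0
                for c in range(4):
                    i0, i1 = gd.off[si, c], gd.off[si, c + 1]
                    cnt = i1 - i0
                    a = point[f"{g}:b[{s},{c}]"] if model.cb > 1 else point[f"{g}:b[{s}]"]
                    v = point[f"{g}:v[{s},{c}]"] if model.cv > 1 else point[f"{g}:v[{s}]"]
                    sgn = np.where(gd.sr[i0:i1], 1.0, -1.0)
                    b_tr[pos : pos + cnt] = a
                    v_tr[pos : pos + cnt] = v * sgn
                    cond_of[pos : pos + cnt] = c
                    pos += cnt
                rt_s, up_s, _ = simulate_trials(
                    b_tr, v_tr, W_FIXED, t0, dt, 20.0, int(rng.integers(2**31 - 1))
                )
                for c in range(4):
                    mask = cond_of == c
                    rep_rt[c].append(rt_s[mask])
                    rep_up[c].append(up_s[mask])
            for c in range(4):
                rts = np.concatenate(rep_rt[c])
                ups = np.concatenate(rep_up[c])
                sim_q[k, c] = np.quantile(rts, PPC_QUANTILES)
                sim_choice[k, c] = ups.mean()
        out[g] = {
            "quantile_probs": list(PPC_QUANTILES),
            "observed_rt_quantiles": obs_q.tolist(),
            "observed_choice_right": obs_choice.tolist(),
            "simulated_rt_quantiles_lo": np.quantile(sim_q, 0.025, axis=0).tolist(),
            "simulated_rt_quantiles_hi": np.quantile(sim_q, 0.975, axis=0).tolist(),
            "simulated_choice_lo": np.quantile(sim_choice, 0.025, axis=0).tolist(),
            "simulated_choice_hi": np.quantile(sim_choice, 0.975, axis=0).tolist(),
            "n_sims": n_sims,
        }
    return out


def diagnostics(
    samples: PosteriorSamples,
    model: HierarchicalModel,
    ppc: dict | None = None,
) -> FitDiagnostics:
    d, p_d = dic(samples, model)
    rh = rhat(samples) if samples.draws.shape[0] >= 2 else {}
    return FitDiagnostics(
        variant=model.variant.name,
        dic=d,
        p_d=p_d,
        rhat=rh,
        ppc_summaries=ppc,
        data_id=model.data_id,
        meta=dict(samples.meta),
    )


def compare_models(fits: list[FitDiagnostics]) -> dict:
    """Rank fitted variants by ascending DIC (lower is better).

    All fits must come from the same dataset; ties are reported explicitly.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ids = {f.data_id for f in fits}
    if len(ids) > 1:
        raise ValueError("fits were computed on different datasets; comparison is meaningless")
    ranked = sorted(fits, key=lambda f: f.dic)
    pairwise = {
        f"{a.variant} - {b.variant}": a.dic - b.dic
        for i, a in enumerate(ranked)
        for b in ranked[i + 1 :]
    }
    ties = [
        (a.variant, b.variant)
        for i, a in enumerate(ranked)
        for b in ranked[i + 1 :]
        if abs(a.dic - b.dic) < 1e-9
    ]
    return {
        "ranking": [f.variant for f in ranked],
        "winner": ranked[0].variant,
        "dic": {f.variant: f.dic for f in fits},
        "p_d": {f.variant: f.p_d for f in fits},
        "delta_dic": pairwise,
        "ties": ties,
    }


def save_fit(
    samples: PosteriorSamples,
    diag: FitDiagnostics,
    csv_path,
    json_path,
    priors: PriorSpec | None = None,
) -> None:
    """Persist draws as long CSV and the fit report/metadata as JSON."""
    samples.to_dataframe().to_csv(csv_path, index=False)
    report = {
        "variant": diag.variant,
        "dic": diag.dic,
        "p_d": diag.p_d,
        "rhat_max": max(diag.rhat.values()) if diag.rhat else None,
        "rhat": diag.rhat,
        "data_id": diag.data_id,
        "seed": samples.seed,
        "n_burn": samples.n_burn,
        "priors": vars(priors) if priors is not None else None,
        "meta": diag.meta,
    }
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)


def load_fit(csv_path, json_path) -> tuple[PosteriorSamples, FitDiagnostics]:
    """Reload a persisted fit (inverse of :func:`save_fit`)."""
    long = pd.read_csv(csv_path)
    names = list(dict.fromkeys(long["parameter"]))  # first-seen order
    n_chains = int(long["chain"].max()) + 1
    n_iter = int(long["iter"].max()) + 1
    idx = {n: i for i, n in enumerate(names)}
    draws = np.empty((n_chains, n_iter, len(names)))
    draws[long["chain"].to_numpy(), long["iter"].to_numpy(),
          long["parameter"].map(idx).to_numpy()] = long["value"].to_numpy()
    with open(json_path) as fh:
        r = json.load(fh)
    samples = PosteriorSamples(
        draws=draws, param_names=names, n_burn=r.get("n_burn", 0),
        deviance=np.zeros((n_chains, n_iter)), seed=r.get("seed"),
        meta=r.get("meta", {}),
    )
    diag = FitDiagnostics(r["variant"], r["dic"], r["p_d"], r.get("rhat", {}),
                          None, r["data_id"], r.get("meta", {}))
    return samples, diag
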