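"""End-to-end orchestration: generate -> filter -> fit -> compare -> analyze -> report.

A run is fully determined by a :class:`RunConfig`: one master seed is split
hierarchically (cohort generation, each variant's sampler, the overlap and
posterior-predictive resamplers draw from named substreams), so identical
config + seed reproduces the report byte-for-byte and single stages can be
rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference as inf
from . import stats as bst
from .cohort import CohortSpec, default_spec, generate_cohort
from .io import write_ground_truth, write_trials

__all__ = ["RunConfig", "MCMC_PROFILES", "run_pipeline"]

log = logging.getLogger("tempoprep")

#: sampler settings per profile; 'production' mirrors the emulated study's
#: 50,000-sample / 5,000-burn-in runs, 'reduced' is the documented scaled-down
#: profile for demos and continuous testing.
MCMC_PROFILES = {
    "production": {"n_samples": 50_000, "n_burn": 5_000, "n_chains": 2},
    "reduced": {"n_samples": 4_000, "n_burn": 1_000, "n_chains": 2},
}


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=default_spec)
    variants: tuple = ("M1_boundary", "M2_drift", "M3_both")
    profile: str = "reduced"
    seed: int = 0
    out_dir: str | Path = "tempoprep_run"
    run_ppc: bool = False
    n_ppc: int = 500
    drop_error_trials: bool = False

    def validate(self) -> None:
        if not self.variants:
            raise ValueError("config lists no model variants to fit")
        unknown = [v for v in self.variants if v not in inf.VARIANTS]
        if unknown:
            raise ValueError(f"unknown model variants: {unknown}")
        if self.profile not in MCMC_PROFILES:
            raise ValueError(f"unknown MCMC profile {self.profile!r}; choose from {sorted(MCMC_PROFILES)}")
        self.cohort.validate()


def _sub_seed(master: int, label: str) -> int:
    """Named substream seed below 2^31, stable across processes (CRC32 of
    the label; Python's built-in str hash is salted per interpreter run)."""
    h = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and emit a single JSON-serialisable report.

    Persists every intermediate artifact under ``config.out_dir``: the trial
    table, the ground-truth sidecar, per-variant posterior draws and fit
    reports, and ``report.json``.  Aborts naming the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        cohort_spec = config.cohort
        cohort_spec.seed = _sub_seed(config.seed, "cohort") if config.seed else cohort_spec.seed
        trials, truth = generate_cohort(cohort_spec)
        write_trials(trials, out / "trials.csv")
        write_ground_truth(truth, out / "ground_truth.csv")
        log.info("generated %d trials for %d groups", len(trials), trials["group"].nunique())

        stage = "filter"
        trials = bst.apply_rt_filter(trials, drop_errors=config.drop_error_trials)
        write_trials(trials, out / "trials_filtered.csv")
        filter_counts = (
            trials.groupby("subject_id")["valid"].agg(["size", "sum"]).assign(
                excluded=lambda d: d["size"] - d["sum"]
            )["excluded"].to_dict()
        )
        log.info("filter excluded %d trials", int(sum(filter_counts.values())))

        stage = "fit"
        profile = MCMC_PROFILES[config.profile]
        fits: dict[str, inf.FitDiagnostics] = {}
        posteriors: dict[str, inf.PosteriorSamples] = {}
        for variant in config.variants:
            model = inf.build_model(variant, trials)
            samples = inf.fit_mcmc(
                model, seed=_sub_seed(config.seed, f"fit:{variant}"), **profile
            )
            ppc = None
            if config.run_ppc:
                ppc = inf.posterior_predictive_check(
                    samples, model, n_sims=config.n_ppc,
                    seed=_sub_seed(config.seed, f"ppc:{variant}"),
                )
            diag = inf.diagnostics(samples, model, ppc)
            inf.save_fit(samples, diag, out / f"posterior_{variant}.csv",
                         out / f"fit_{variant}.json", priors=model.priors)
            fits[variant] = diag
            posteriors[variant] = samples
            log.info("fitted %s: DIC=%.1f max R-hat=%.3f", variant, diag.dic,
                     max(diag.rhat.values()) if diag.rhat else float("nan"))

        stage = "compare"
        if len(fits) >= 2:
            comparison = inf.compare_models(list(fits.values()))
        else:
            only = next(iter(fits))
            comparison = {"ranking": [only], "winner": only,
                          "dic": {only: fits[only].dic}, "delta_dic": {}, "ties": []}
        winner = comparison["winner"]

        stage = "analyze"
        analysis = analyze(
            trials, posteriors[winner],
            seed=_sub_seed(config.seed, "analyze"), truth=truth,
        )
        tidy = [
            {"subject_id": r["subject_id"], "group": r["group"], "analysis": kind,
             "beta0": r["beta0"], "beta1": r["beta1"], "r2": r["r2"]}
            for kind in ("poisson", "foreperiod", "boundary")
            for r in analysis["per_subject"][kind]
        ]
        pd.DataFrame(tidy).to_csv(out / "regressions.csv", index=False)

        stage = "report"
        report = {
            "config": {
                "seed": config.seed,
                "profile": config.profile,
                "sampler": {
                    "algorithm": "adaptive Metropolis-within-Gibbs, scales tuned during burn-in only",
                    **profile,
                },
                "variants": list(config.variants),
                "n_subjects_per_group": cohort_spec.n_subjects_per_group,
                "n_trials_per_session": cohort_spec.n_blocks * cohort_spec.n_trials_per_block,
                "conventions": {
                    "diffusion_coefficient": 1.0,
                    "time_unit": "seconds (ms at I/O)",
                    "start_point": "z/b fixed at 0.5",
                    "predictor": "x = 4 - tp_rank (x=0 at highest predictability)",
                    "rt_filter": "rt < 100 ms or rt > median + 3*MAD (raw, one-sided) invalid",
                    "overlap_threshold": bst.bonferroni_threshold(),
                },
            },
            "filter_excluded_per_subject": filter_counts,
            "dic_table": comparison["dic"],
            "delta_dic": comparison["delta_dic"],
            "winning_model": winner,
            "rhat_max": {v: (max(f.rhat.values()) if f.rhat else None) for v, f in fits.items()},
            "analysis": analysis,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc


def analyze(
    trials: pd.DataFrame,
    samples: inf.PosteriorSamples,
    seed: int = 0,
    truth: pd.DataFrame | None = None,
) -> dict:
    """Behavioural + model-parameter analysis layer over a fitted posterior.

    Per subject: Poisson RT regression on predictability, foreperiod-effect
    OLS slope, boundary regression on posterior-mean boundaries.  Per group:
    one-sample t-tests of slopes against zero (one-sided: slowing with lower
    predictability), between-group ANOVA with Welch post-hocs, posterior
    overlap q for the group-level means, Spearman boundary-RT correlation
    (Fisher-z reported).  When ground truth is supplied, recovery metrics
    (correlations and group-mean coverage) are added.
    """
    valid = trials[trials["valid"]]
    groups = sorted(valid["group"].unique())
    poisson = bst.subject_regressions(trials, "poisson")
    fp = bst.subject_regressions(trials, "foreperiod")

    # per-subject boundary regressions from posterior-mean boundaries
    post_mean = samples.posterior_mean()
    b_varies = any(",0]" in n and ":b[" in n for n in samples.param_names)
    boundary_rows = []
    for g in groups:
        subjects = sorted(valid[valid["group"] == g]["subject_id"].unique())
        for s in subjects:
            if b_varies:
                bvals = [post_mean[f"{g}:b[{s},{c}]"] for c in range(4)]
            else:
                bvals = [post_mean[f"{g}:b[{s}]"]] * 4
            res = bst.boundary_regression(bvals, [4 - c for c in range(4)])
            boundary_rows.append(
                {"subject_id": s, "group": g, "beta0": res.beta0, "beta1": res.beta1,
                 "r2": res.r_squared, "b_by_x": bvals}
            )
    boundary = pd.DataFrame(boundary_rows)

    def group_summary(df: pd.DataFrame, expify: bool = False) -> dict:
        outp = {}
        for g in groups:
            sub = df[df["group"] == g]
            b0 = np.exp(sub["beta0"]) if expify else sub["beta0"]
            outp[g] = {
                "intercept_mean": float(np.mean(b0)),
                "intercept_sd": float(np.std(b0, ddof=1)) if len(sub) > 1 else 0.0,
                "slope_mean": float(sub["beta1"].mean()),
                "slope_sd": float(sub["beta1"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "slope_vs_zero": _test_dict(
                    bst.group_tests(sub["beta1"].to_numpy(), "one_sample_t", alternative="greater")
                ),
            }
        return outp

    def between_group(df: pd.DataFrame, col: str) -> dict:
        arrays = [df[df["group"] == g][col].to_numpy() for g in groups]
        outp = {}
        if len(groups) >= 3:
            outp["anova"] = _test_dict(bst.group_tests(arrays, "anova"))
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                res = bst.group_tests([arrays[i], arrays[groups.index(gb)]], "welch_posthoc")
                outp[f"{ga} vs {gb}"] = _test_dict(res)
        return outp

    # Spearman boundary-RT correlation per group, across subject-condition cells
    spearman = {}
    for g in groups:
        sub_b = boundary[boundary["group"] == g]
        bs, rts = [], []
        for _, row in sub_b.iterrows():
            for c in range(4):
                cell = valid[
                    (valid["group"] == g)
                    & (valid["subject_id"] == row["subject_id"])
                    & (valid["tp_rank"] == 4 - c)
                ]
                if len(cell):
                    bs.append(row["b_by_x"][c])
                    rts.append(float(cell["rt_ms"].mean()))
        rho = bst.spearman_boundary_rt(bs, rts)
        rho_c = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
        spearman[g] = {"rho": rho, "fisher_z": bst.fisher_z(rho_c), "n_pairs": len(bs)}

    overlap = {}
    if len(groups) >= 2:
        suffixes = ["mu_t0"]
        suffixes += [f"mu_b[{c}]" for c in range(4)] if b_varies else ["mu_b"]
        for sfx in suffixes:
            try:
                overlap[sfx] = inf.group_overlap_matrix(samples, sfx, seed=seed)
            except KeyError:
                continue

    result = {
        "poisson_regression": group_summary(poisson, expify=True),
        "poisson_between_groups": between_group(poisson, "beta1"),
        "foreperiod_effect": group_summary(fp),
        "boundary_regression": group_summary(boundary),
        "boundary_between_groups": between_group(boundary, "beta1"),
        "spearman_boundary_rt": spearman,
        "overlap_q": overlap,
        "per_subject": {
            "poisson": poisson.drop(columns=["analysis"]).to_dict("records"),
            "foreperiod": fp.drop(columns=["analysis"]).to_dict("records"),
            "boundary": boundary.drop(columns=["b_by_x"]).to_dict("records"),
        },
    }
    if truth is not None and len(truth):
        result["recovery"] = _recovery_metrics(boundary, samples, truth, groups)
    return result


def _recovery_metrics(boundary: pd.DataFrame, samples, truth: pd.DataFrame, groups) -> dict:
    tw = truth.pivot_table(index=["group", "subject_id"], columns="parameter", values="value")
    est0, est1, tru0, tru1 = [], [], [], []
    for _, row in boundary.iterrows():
        key = (row["group"], row["subject_id"])
        if key in tw.index and "b_intercept" in tw.columns:
            est0.append(row["beta0"])
            est1.append(row["beta1"])
            tru0.append(tw.loc[key, "b_intercept"])
            tru1.append(tw.loc[key, "b_slope"])
    out: dict = {}
    if len(est0) >= 3:
        out["r_boundary_intercept"] = float(np.corrcoef(est0, tru0)[0, 1])
        out["r_boundary_slope"] = float(np.corrcoef(est1, tru1)[0, 1])
        out["n_subjects"] = len(est0)
    # coverage of group-level boundary means
    coverage = {}
    for g in groups:
        gt = tw.loc[g] if g in tw.index.get_level_values(0) else None
        if gt is None or "b_tp4" not in tw.columns:
            continue
        covered = []
        for c in range(4):
            name = f"{g}:mu_b[{c}]"
            if name not in samples.param_names:
                continue
            lo, hi = samples.credible_interval(name)
            true_mean = float(gt[f"b_tp{4 - c}"].mean())
            covered.append(bool(lo <= true_mean <= hi))
        if covered:
            coverage[g] = {"covered": covered, "fraction": float(np.mean(covered))}
    if coverage:
        out["group_boundary_ci_coverage"] = coverage
    return out


def _test_dict(t) -> dict:
    df = list(t.df) if isinstance(t.df, tuple) else t.df
    return {"statistic": t.statistic, "df": df, "p": t.p,
            "effect_size": t.effect_size, "effect_label": t.effect_label}
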