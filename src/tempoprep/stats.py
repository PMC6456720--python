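"""Trial filtering and the regression / frequentist analysis layer.

Per-subject analyses:

* ``filter_rts`` — the outlier rule: responses faster than 100 ms or
  exceeding the subject's median RT by more than 3 raw median absolute
  deviations are invalid.
* ``poisson_regression`` — log-link Poisson regression of RT (integer ms) on
  recoded temporal predictability x = 4 - tp_rank, so exp(beta0) is the
  expected RT at the most predictable level and beta1 > 0 means slowing as
  predictability falls.
* ``foreperiod_slope`` — OLS slope of RT on foreperiod length; negative
  slopes are the classic foreperiod effect (faster responses late in the
  trial).
* ``boundary_regression`` — OLS line through the fitted boundary values over
  the same recoded predictor.

Group-level frequentist tests (one-way ANOVA with eta-squared, Welch
post-hocs, paired/one-sample/two-sample t-tests with Cohen's d_z) and the
Spearman boundary-RT correlation with Fisher's z transform round out the
layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "GroupTestResult",
    "filter_rts",
    "poisson_regression",
    "foreperiod_slope",
    "boundary_regression",
    "group_tests",
    "spearman_boundary_rt",
    "fisher_z",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class RegressionResult:
    beta0: float
    beta1: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.r_squared) or 0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: float | tuple
    p: float
    effect_size: float
    effect_label: str


def filter_rts(rts) -> np.ndarray:
    """Validity mask for one subject-session's RTs (ms).

    Invalid iff rt < 100 ms or rt > median + 3 * MAD, where MAD is the raw
    (unscaled) median absolute deviation of that subject's RTs.  The upper
    cut is one-sided and the boundary is kept inclusive, so with zero spread
    everything at the median survives.  Idempotent: re-filtering survivors
    removes nothing.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot filter an empty RT set")
    med = np.median(rts)
    mad = np.median(np.abs(rts - med))
    return (rts >= 100.0) & (rts <= med + 3.0 * mad)


def recode_predictability(tp_rank) -> np.ndarray:
    """x = 4 - tp_rank in {0..3}; x = 0 at the highest predictability."""
    return 4.0 - np.asarray(tp_rank, dtype=float)


def poisson_regression(rts, tp_rank) -> RegressionResult:
    """Per-subject Poisson (log-link) regression of RT on predictability.

    RTs are rounded to integer milliseconds and treated as the count
    response (quasi-likelihood: overdispersion inflates standard errors but
    not the point estimates, and only the point estimates feed downstream
    group tests).
    """
    rts = np.asarray(rts, dtype=float)
    x = recode_predictability(tp_rank)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct predictability levels")
    if np.any(rts <= 0):
        raise ValueError("non-positive RT passed to poisson_regression; filter first")
    y = np.round(rts)
    X = sm.add_constant(x)
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = fit.fittedvalues
    # deviance-based fraction of explained variation, clipped into [0, 1]
    null_dev = sm.GLM(y, np.ones_like(y), family=sm.families.Poisson()).fit().deviance
    r2 = float(np.clip(1.0 - fit.deviance / null_dev, 0.0, 1.0)) if null_dev > 0 else 0.0
    return RegressionResult(float(fit.params[0]), float(fit.params[1]), r2)


def foreperiod_slope(rts, foreperiods) -> RegressionResult:
    """OLS regression of RT (ms) on foreperiod length (ms), per subject."""
    rts = np.asarray(rts, dtype=float)
    fp = np.asarray(foreperiods, dtype=float)
    if np.unique(fp).size < 2:
        raise ValueError("need at least two distinct foreperiods")
    res = sps.linregress(fp, rts)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return RegressionResult(float(res.intercept), float(res.slope), r2)


def boundary_regression(boundaries, tp_rank) -> RegressionResult:
    """OLS line through one subject's fitted boundaries over x = 4 - tp_rank.

    Expects exactly one boundary per condition; the intercept is the boundary
    at the highest temporal predictability.
    """
    b = np.asarray(boundaries, dtype=float)
    ranks = np.asarray(tp_rank)
    missing = sorted(set((1, 2, 3, 4)) - set(int(r) for r in ranks))
    if missing:
        raise ValueError(f"missing boundary value for tp_rank {missing}")
    if len(b) != 4:
        raise ValueError("expected exactly one boundary per condition")
    x = recode_predictability(ranks)
    res = sps.linregress(x, b)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return RegressionResult(float(res.intercept), float(res.slope), r2)


def group_tests(values, design: str, *, alternative: str = "two-sided") -> GroupTestResult:
    """Standard frequentist group tests with the study's effect sizes.

    ``values``: for 'anova' a list of per-group arrays; for 'welch_posthoc'
    and 'two_sample_t' a pair of arrays; for 'paired_t' a pair of aligned
    arrays; for 'one_sample_t' a single array (tested against 0).
    Welch post-hocs use the Welch-Satterthwaite fractional df
    (heteroscedasticity correction); eta-squared is reported for ANOVA and
    Cohen's d_z for paired contrasts.
    """
    if design == "anova":
        groups = [np.asarray(g, dtype=float) for g in values]
        if any(g.size < 2 for g in groups):
            raise ValueError("each group needs at least two observations")
        f, p = sps.f_oneway(*groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_total = sum(((g - grand) ** 2).sum() for g in groups)
        eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
        df = (len(groups) - 1, sum(g.size for g in groups) - len(groups))
        return GroupTestResult(float(f), df, float(p), eta2, "eta_squared")
    if design in ("welch_posthoc", "two_sample_t"):
        a, b = (np.asarray(g, dtype=float) for g in values)
        equal_var = design == "two_sample_t"
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        df = float(res.df)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        return GroupTestResult(float(res.statistic), df, float(res.pvalue), d, "cohen_d")
    if design == "paired_t":
        a, b = (np.asarray(g, dtype=float) for g in values)
        if a.shape != b.shape:
            raise ValueError("paired design requires aligned samples of equal length")
        diff = a - b
        res = sps.ttest_rel(a, b, alternative=alternative)
        sd = diff.std(ddof=1)
        dz = float(diff.mean() / sd) if sd > 0 else np.inf * np.sign(diff.mean())
        return GroupTestResult(float(res.statistic), float(a.size - 1), float(res.pvalue), dz, "cohen_dz")
    if design == "one_sample_t":
        a = np.asarray(values, dtype=float)
        res = sps.ttest_1samp(a, 0.0, alternative=alternative)
        sd = a.std(ddof=1)
        dz = float(a.mean() / sd) if sd > 0 else np.inf * np.sign(a.mean())
        return GroupTestResult(float(res.statistic), float(a.size - 1), float(res.pvalue), dz, "cohen_dz")
    raise ValueError(f"unknown design {design!r}")


def spearman_boundary_rt(boundaries, mean_rts) -> float:
    """Spearman rank correlation (mid-rank ties) between fitted boundaries
    and mean RTs across matched subject-condition cells."""
    b = np.asarray(boundaries, dtype=float)
    r = np.asarray(mean_rts, dtype=float)
    if b.size != r.size or b.size < 3:
        raise ValueError("need at least three matched pairs")
    rho, _ = sps.spearmanr(b, r)
    return float(rho)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform arctanh(r); |r| must be < 1."""
    if not abs(r) < 1:
        raise ValueError("|r| must be strictly below 1")
    return float(np.arctanh(r))


def bonferroni_threshold(alpha: float = 0.05, n_comparisons: int = 3) -> float:
    """Corrected significance threshold for the posterior-overlap statistic q
    across the pairwise group contrasts (0.05 / 3 ~ 0.0167 by default)."""
    return alpha / n_comparisons


def subject_regressions(trials: pd.DataFrame, kind: str = "poisson") -> pd.DataFrame:
    """Per-subject regression table over a trial DataFrame (valid trials only).

    kind: 'poisson' (RT ~ predictability) or 'foreperiod' (RT ~ foreperiod).
    Returns a tidy frame (subject_id, group, analysis, beta0, beta1, r2).
    """
    rows = []
    for (subject, group), sub in trials[trials["valid"]].groupby(["subject_id", "group"], sort=True):
        if kind == "poisson":
            res = poisson_regression(sub["rt_ms"], sub["tp_rank"])
        elif kind == "foreperiod":
            res = foreperiod_slope(sub["rt_ms"], sub["foreperiod_ms"])
        else:
            raise ValueError(f"unknown regression kind {kind!r}")
        rows.append(
            {
                "subject_id": subject,
                "group": group,
                "analysis": kind,
                "beta0": res.beta0,
                "beta1": res.beta1,
                "r2": res.r_squared,
            }
        )
    return pd.DataFrame(rows)


def apply_rt_filter(trials: pd.DataFrame, drop_errors: bool = False) -> pd.DataFrame:
    """Apply the RT validity rule per subject-session; returns a copy with the
    ``valid`` column updated.  ``drop_errors`` additionally invalidates trials
    whose response side differs from the stimulus side (the study does not
    state whether error trials entered the RT analyses; the default keeps
    them)."""
    out = trials.copy()
    responded = out["response"].ne("NONE") & out["rt_ms"].notna()
    out["valid"] = responded
    for _, idx in out[responded].groupby(["subject_id", "session"]).groups.items():
        mask = filter_rts(out.loc[idx, "rt_ms"].to_numpy())
        out.loc[idx, "valid"] = mask
    if drop_errors:
        out.loc[out["response"] != out["stimulus"], "valid"] = False
    return out
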