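# Methods

## Model

A trial is modelled as a one-dimensional diffusion X(t) with drift and unit
diffusion coefficient, started at z between absorbing boundaries 0 and b,
with time in seconds.  Under stimulus coding, the lower and upper boundary
map to LEFT and RIGHT responses; the drift is +v when the stimulus calls
for RIGHT and −v when it calls for LEFT, so a single v per subject (or per
condition, depending on variant) measures evidence quality toward the
correct response.  Observed reaction time is the first-passage time plus a
non-decision latency t₀.  The start point is fixed at z = b/2 throughout
(no a-priori response bias: sides are equiprobable and counterbalanced), so
the free parameters are b, v, t₀.

The first-passage density at a boundary is computed by the standard dual
series representation of the Wiener first-passage-time density: a
small-time expansion (Gaussian-image sum) and a large-time expansion
(sine series), with the number of terms computed from the requested
absolute error (default 10⁻⁷ on the normalised density) and the cheaper
expansion selected at each evaluation.  The upper-boundary density uses the
reflection identity f_upper(t | v, z) = f_lower(t | −v, b − z).  Density
below t₀ is zero by contract; impossible data yield a −∞ log-likelihood
sentinel rather than an exception.

The absorption probability at the upper boundary,
P = expm1(−2vz)/expm1(−2vb) with limit z/b as v → 0, is implemented with an
asymptotic branch for strongly negative drift and serves as an internal
consistency oracle for the density (numeric integrals must reproduce it).

## Simulator

First passages are simulated by Euler–Maruyama stepping (default
dt = 10⁻⁴ s) augmented with the Brownian-bridge crossing correction: after
an interior step from x to x′, the walk is declared absorbed with the exact
conditional bridge-crossing probability exp(−2·d·d′/dt) for each boundary.
This removes the O(√dt) first-passage bias of endpoint-only crossing
detection; with the correction, dt = 2.5·10⁻⁴ s passes a 10⁵-draw
Kolmogorov–Smirnov test against the analytic density at α = 0.01, and
cohort generation uses dt = 5·10⁻⁴ s (residual timing bias well under the
1 ms I/O rounding).  Walks not absorbed by t_max = 20 s are returned
flagged censored, never dropped.

## Synthetic cohorts

The generator reproduces the variable-foreperiod design: four blocked
conditions crossing foreperiod duration (means 1500/3000 ms) and
variability (SDs 100/600 ms), truncated symmetrically (500–2500 ms,
2000–4000 ms) so the means are preserved; 4 blocks × 120 trials per
session, block order following a cyclic 4×4 Latin square balanced over
subjects; an optional 40-trial training block with exponential (flat
hazard) foreperiods of mean 1000 ms.  Truncated-Gaussian sampling is by
rejection from the untruncated normal (acceptance ≥ 0.90 in all four
cells) with an exact inverse-CDF fallback.

Temporal predictability ranks the four cells Short/Low = 4, Short/High = 3,
Long/Low = 2, Long/High = 1: uncertainty grows with both duration and
variability, and duration is taken as the dominant factor.  The mapping is
a single configurable table; any monotone alternative can be passed to
`make_condition_grid`.  All regressions use the recoded predictor
x = 4 − Tp, which makes the intercept literally "the expected value at the
highest predictability".

Each subject draws a boundary intercept/slope pair (boundary linear in x),
a drift rate and a non-decision time from group-level normals.  Packaged
group profiles (see `defaults.yaml`) use the emulated study's group-level
boundary estimates: Control 0.869 + 0.040·x, PD-on 0.931 + 0.059·x,
PD-off 1.065 + 0.001·x, with between-subject SDs as published.  Drift and
non-decision time are not published; v = 4.0 s⁻¹ (SD 0.4) and t₀ = 0.25 s
place the simulated mean RTs in the study's 330–400 ms band with ~97%
choice accuracy, and the between-subject t₀ SD is set small (0.01 s) so
that individual RT differences are boundary-driven — the study's own
report that boundary changes alone account for RT differences, and its
boundary–RT Spearman correlations near 0.8, are inconsistent with a large
non-decision spread.  An optional drift slope over x supports generating
drift-varying cohorts for model-recovery studies; an optional lapse rate
(default 0) injects response-less trials for filter testing; an optional
hazard sensitivity (`fp_hazard`, default 0) shrinks the boundary linearly
over the foreperiod's position within its condition range, producing the
classic within-trial foreperiod effect (faster late responses) for
sign-check studies.

What the generator does **not** emulate: session-order, learning and
fatigue effects; sequential (trial-history) dependencies; across-trial
parameter variability (the fitted model has none either); any coupling
between a subject's boundary, drift and non-decision time; non-diffusion
contaminant responses beyond the optional lapse trials.  Passing recovery
tests therefore demonstrates the estimator works when the model is true,
not that real patient data are this clean.

## RT validity rule

Within each subject-session, a response is invalid iff RT < 100 ms or
RT > median + 3·MAD, with the raw (unscaled) median absolute deviation and
an inclusive boundary.  The rule is one-sided above, exactly as worded in
the protocol it implements, and is applied in a single pass.  It is *not*
mathematically idempotent: trimming the slow tail lowers the median and
MAD, so a second pass may remove more; the filter is deliberately a single
pass.  Whether error (wrong-side) trials enter RT analyses is exposed as a
switch (`drop_errors`, default off).

## Hierarchical inference

Each group is an independent hierarchy (no shared hyperpriors): subject
parameters are normal around group means with a shared group SD per
parameter family.  Priors are weakly informative — group-mean
b ~ N(1.5, 0.75) on positive support, v ~ N(2, 3),
t₀ ~ N(0.3, 0.25) positive, group SDs half-normal(0.5) — wide enough to
cover the human two-choice regime without dominating a 480-trial subject.
Subject-level supports (b > 0, 0 < t₀ < min RT) are enforced by proposal
rejection; the truncated-normal normalising constants this leaves out of
the hyperparameter updates are negligible at the fitted mean/SD ratios
(≥ 6 SD from the bound).

Sampling is adaptive Metropolis-within-Gibbs: random-walk updates per
scalar parameter, proposal scales tuned toward ~35% acceptance during
burn-in only (so the post-burn-in kernel is fixed and valid).  Because the
centred parameterisation mixes slowly when a group mean and its subject
values must move together, each sweep adds joint translation moves that
shift a group mean and all its subject values by one common delta; these
leave the subject-deviation prior terms unchanged and cost one likelihood
pass, and they restore prior sampling when the likelihood is silenced
(the prior-recovery smoke test).  Everything is deterministic given the
seed; chains and groups draw from independently spawned seed streams.

The production profile mirrors the emulated analysis (50,000 samples,
5,000 burn-in); the reduced profile (4,000/1,000, 2 chains) is the
documented scaled-down setting used by the demo, the test suite and the
acceptance script.  Convergence is summarised by the classic Gelman–Rubin
potential scale reduction (between/within-chain variance ratio; an
independent cross-check against arviz's rank-normalised variant is part of
the test suite).  Model comparison uses the conditional DIC focused on the
subject-level parameters: D̄ is the posterior mean deviance recorded
during sampling, p_D = D̄ − D(θ̄) at the posterior mean, DIC = D̄ + p_D;
this is the standard focus for hierarchical diffusion fitting and is
recorded in the fit metadata.  Posterior predictive checks simulate full
replicate datasets from thinned posterior draws and compare observed RT
quantiles (10/30/50/70/90%) and choice proportions per group × condition
against the simulated central 95% bands.

Group inference uses q = 2·min(P̂(θ_A > θ_B), P̂(θ_A < θ_B)) by paired
resampling of posterior draws.  The underlying protocol describes q
loosely as a "proportion of overlap"; the doubled two-sided exceedance
probability is a declared design choice that reproduces the intended
decision logic (q ≈ 1 for indistinguishable posteriors, q = 0 for disjoint
ones) and is symmetric and shift-invariant.  Its significance threshold is
0.05/3 ≈ 0.0167, Bonferroni over the three pairwise group contrasts.

## Behavioural layer

The Poisson regression treats RT rounded to integer milliseconds as the
count response of a log-link GLM in x (quasi-likelihood: overdispersion
inflates standard errors, not the point estimates, and only the point
estimates feed the downstream group tests).  It is fitted at trial level;
condition means are a config option since the original granularity is not
documented.  The foreperiod effect is the per-subject OLS slope of RT on
foreperiod length (negative = classic speed-up late in the trial).  The
boundary regression is the per-subject OLS line through the four
posterior-mean boundaries over x.  Group tests: one-way ANOVA with η²,
Welch post-hocs (heteroscedasticity-corrected fractional df), paired and
one-sample t-tests with Cohen's d_z; slope-vs-zero tests are one-sided
(the directional hypothesis is slowing with lower predictability).
Boundary–RT correspondence is Spearman's ρ over subject × predictability
cells (posterior-mean boundary vs mean valid RT), Fisher-z transformed
where parametric tests across groups are wanted.

## Problem sizes

The test suite runs reduced fits throughout: shared fixtures use 4
subjects × 240 trials; the acceptance checks use the full study geometry
(16 subjects × 480 trials) for parameter recovery and the three-group
pipeline, 8 subjects per cohort for the two-way model-recovery study, and
three seeds wherever an average over replications is asserted.  The
acceptance script mirrors those sizes.

## Known limitations

- No across-trial variability parameters and no contaminant mixture; real
  RT data usually need at least one of these.
- The sampler is random-walk based; it is robust with the series
  likelihood but less efficient than gradient-based samplers for large
  cohorts.  Production-scale runs (50k samples, 3 groups, 3 variants) take
  tens of minutes.
- DIC is the only comparison criterion (as in the emulated analysis);
  WAIC/LOO would need pointwise likelihood storage and are future work.
- The posterior-overlap q is one defensible formalisation among several;
  conclusions near the 0.0167 threshold should not be read as sharp.
- With small cohorts the one-sided slope tests are sensitive to the
  between-subject slope SD (0.05, as published): single seeds can miss
  significance for a truly positive group-mean slope.
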