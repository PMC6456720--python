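# tempoprep

Temporal preparation under variable foreperiods: synthetic cohorts,
hierarchical Bayesian drift-diffusion modelling, and the behavioural
regression layer for group comparisons (healthy controls vs Parkinson's
disease patients on and off dopaminergic medication).

## The problem

In a variable-foreperiod task, a warning stimulus precedes an imperative
stimulus by a delay (the *foreperiod*) drawn from a blocked 2×2 design:
mean duration (Short 1500 ms / Long 3000 ms) crossed with variability
(SD 100 / 600 ms), each Gaussian truncated symmetrically around its mean
(500–2500 ms and 2000–4000 ms).  Each cell carries an ordinal temporal
predictability rank Tp ∈ {1..4}.  Healthy subjects speed up when stimulus
onset is predictable; the question is which latent decision-process change
carries that speed-up, and how dopamine depletion alters it.

The decision model is a two-boundary drift-diffusion process under
*stimulus coding* (lower/upper boundary = left/right response) with
parameters b (boundary separation), v (drift rate), z (start point, fixed
at z/b = 1/2), and t₀ (non-decision time).  Three hierarchical variants
compete: only b varies across predictability levels (Model 1), only v
(Model 2), or both (Model 3), compared by DIC.  Group differences in
posterior parameters use the overlap statistic

    q = 2 · min( P(θ_A > θ_B), P(θ_A < θ_B) ),

significant below the Bonferroni-corrected threshold 0.05/3 ≈ 0.0167.
The behavioural layer fits, per subject, a Poisson (log-link) regression

    log E[RT | Tp] = β₀ + β₁ · x,   x = 4 − Tp,

so exp(β₀) is the expected RT at the highest predictability and β₁ > 0
means slowing as predictability falls; plus an OLS foreperiod-effect slope
(RT on foreperiod length) and an OLS line through each subject's fitted
boundaries over x.

Because no raw patient data ships with this package, a first-class
synthetic-cohort generator stands in for it: subject-level diffusion
parameters are drawn around group-level profiles (boundary intercept/slope
over x taken from the emulated study's group estimates), and every trial's
choice and RT come from the diffusion simulator, so parameter-recovery
studies can score the fitted estimates against known ground truth.

## Worked example

```sh
tempoprep demo --seed 1 --out demo_out
```

runs the whole chain at the reduced MCMC profile (4,000 samples / 1,000
burn-in, 2 chains) on an 8-subject-per-group synthetic cohort and prints:

```
winning model: M1_boundary
Control: RT intercept 341 ms, predictability slope 0.0107 (p=0.0440 one-sided)
PD-off: RT intercept 355 ms, predictability slope 0.0048 (p=0.1611 one-sided)
PD-on: RT intercept 345 ms, predictability slope 0.0205 (p=0.0002 one-sided)
```

Reading: DIC prefers the boundary-only variant on boundary-generated data
(model recovery works); the Control-like and PD-on-like cohorts show
significantly positive Poisson slopes — their RTs track temporal
predictability — while the flat PD-off-like cohort does not, reproducing
the qualitative dopamine-depletion pattern the generator encodes.  All
artifacts (trial CSV, ground-truth sidecar, posterior draws, fit reports,
`report.json`) land in `demo_out/`.

The same chain is available from Python:

```python
from tempoprep import RunConfig, run_pipeline, default_spec

cfg = RunConfig(cohort=default_spec(), variants=("M1_boundary", "M2_drift"),
                profile="reduced", seed=1, out_dir="run")
report = run_pipeline(cfg)
print(report["winning_model"], report["dic_table"])
```

Short narrative scripts in `examples/` cover each capability: task design
and foreperiod sampling, diffusion simulation vs the analytic density,
a single hierarchical fit with recovery scoring, and model comparison.

## Layout

- `src/tempoprep/design.py` — 2×2 foreperiod conditions, truncated-Gaussian
  sampling, Latin-square session schedules, exponential training block
- `src/tempoprep/cohort.py` — synthetic multi-group cohorts + ground truth
- `src/tempoprep/ddm.py`, `_kernels.py` — simulator, Wiener first-passage
  density (dual series), trial log-likelihood (numba-compiled kernels)
- `src/tempoprep/inference.py` — hierarchical model, adaptive
  Metropolis-within-Gibbs, R-hat, DIC, posterior predictive checks, overlap q
- `src/tempoprep/stats.py` — RT filter, Poisson/foreperiod/boundary
  regressions, ANOVA/t-tests with η² and Cohen's d_z, Spearman, Fisher z
- `src/tempoprep/pipeline.py`, `cli.py` — orchestration and the `tempoprep`
  command (`generate`, `filter`, `fit`, `compare`, `analyze`, `report`,
  `run`, `demo`)

See `docs/methods.md` for the model, priors, numerical choices and known
limitations.
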