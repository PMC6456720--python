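"""Behavioural layer: RT filter, Poisson regression, foreperiod effect.

Generates the packaged three-group cohort (small size), applies the
validity rule, and runs the per-subject regressions plus group tests,
without any model fitting.
"""

import numpy as np

from tempoprep import stats as bst
from tempoprep.cohort import default_spec, generate_cohort

trials, _ = generate_cohort(default_spec(n_subjects_per_group=8, seed=42))
trials = bst.apply_rt_filter(trials)
print(f"{len(trials)} trials; {(~trials['valid']).mean():.1%} excluded "
      "(<100 ms or > median + 3 MAD, per subject)")

pois = bst.subject_regressions(trials, "poisson")
fp = bst.subject_regressions(trials, "foreperiod")

print("\nPoisson regression log E[RT] = b0 + b1 * (4 - Tp), per group:")
for g, sub in pois.groupby("group"):
    t = bst.group_tests(sub["beta1"].to_numpy(), "one_sample_t", alternative="greater")
    print(f"  {g:<8} exp(b0) = {np.exp(sub['beta0']).mean():5.0f} ms   "
          f"b1 = {sub['beta1'].mean():+.4f}  (slope > 0: p = {t.p:.4f})")

print("\nforeperiod effect (OLS slope of RT on foreperiod, ms/ms):")
for g, sub in fp.groupby("group"):
    print(f"  {g:<8} mean slope {sub['beta1'].mean():+.4f} "
          "(negative = faster late in the trial)")

anova = bst.group_tests(
    [sub["beta1"].to_numpy() for _, sub in pois.groupby("group")], "anova")
print(f"\nbetween-group ANOVA on Poisson slopes: F{anova.df} = "
      f"{anova.statistic:.2f}, p = {anova.p:.4f}, eta^2 = {anova.effect_size:.3f}")
print("-> slopes index how strongly RT tracks temporal predictability; the")
print("   PD-off-like cohort is generated with a flat boundary profile, so its")
print("   mean slope sits near zero. Group tests at this small size (8 per")
print("   group) are noisy; the full-size pipeline uses 16 subjects per group.")
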