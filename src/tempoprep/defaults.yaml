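# Generative defaults for synthetic cohorts.
#
# Boundary intercept/slope means and between-subject SDs follow the
# group-level model estimates of the study being emulated (Control, PD on
# medication, PD off medication).  Drift and non-decision time are not
# reported there; v = 4.0 /s and t0 = 0.25 s place simulated mean RTs in the
# 330-400 ms band of the behavioural intercepts, with group differences
# carried by the boundary profile alone.
n_subjects_per_group: 16
n_blocks: 4
n_trials_per_block: 120
lapse_rate: 0.0
seed: 12345
simulation:
  dt: 0.0005      # Euler-Maruyama step, seconds
  t_max: 20.0     # censoring cap, seconds
groups:
  Control:
    b_intercept: 0.869
    b_slope: 0.040
    v: 4.0
    t0: 0.25
    sds: {b_intercept: 0.16, b_slope: 0.05, v: 0.4, t0: 0.01}
  PD-on:
    b_intercept: 0.931
    b_slope: 0.059
    v: 4.0
    t0: 0.25
    sds: {b_intercept: 0.10, b_slope: 0.05, v: 0.4, t0: 0.01}
  PD-off:
    b_intercept: 1.065
    b_slope: 0.001
    v: 4.0
    t0: 0.25
    sds: {b_intercept: 0.14, b_slope: 0.05, v: 0.4, t0: 0.01}
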