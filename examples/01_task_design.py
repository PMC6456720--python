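"""The variable-foreperiod task: conditions, schedules, training block.

Builds the 2x2 design, draws foreperiods from each truncated Gaussian, and
lays out one session; prints the empirical means (symmetric truncation must
leave them at the nominal 1500/3000 ms) and the block structure.
"""

import numpy as np

from tempoprep import design

rng = np.random.Generator(np.random.PCG64(0))

print("condition grid (mu/sigma/truncation, predictability rank):")
for cond in design.make_condition_grid():
    draws = design.sample_foreperiod(cond, rng, size=50_000)
    print(
        f"  {cond.label:<11} N({cond.mu:.0f}, {cond.sigma:.0f}) on "
        f"[{cond.lower:.0f}, {cond.upper:.0f}]  Tp={cond.tp_rank}  "
        f"empirical mean {draws.mean():7.1f} ms, SD {draws.std():5.1f} ms"
    )
print("-> symmetric truncation keeps the means at 1500/3000 ms; the high-")
print("   variability SDs shrink below 600 ms because the tails are cut.\n")

sched = design.build_session_schedule(design.make_condition_grid(), 4, 120, 0, rng)
blocks = {}
for block, cond, fp, stim in sched:
    blocks.setdefault(block, cond.label)
print(f"one session: {len(sched)} trials in 4 blocks, order {blocks}")

train = design.generate_training_block(40, rng)
fps = [t["foreperiod_ms"] for t in train]
print(f"training block: {len(train)} trials, exponential foreperiods, "
      f"mean {np.mean(fps):.0f} ms (flat hazard: elapsed time is uninformative)")
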