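"""Synthetic multi-group cohorts with known ground-truth diffusion parameters.

A cohort emulates the variable-foreperiod experiment: per group, each subject
receives a boundary profile linear in recoded temporal predictability
``x = 4 - tp_rank`` (x = 0 at the most predictable cell), a single drift rate
and a single non-decision time, and two-choice responses are generated by the
two-boundary diffusion simulator.  The ground-truth parameter table is
returned alongside the trial table so that parameter-recovery studies can
score the fitted estimates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import design
from ._kernels import simulate_trials

__all__ = ["GroupTruth", "CohortSpec", "generate_cohort", "default_spec"]

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "block",
    "duration_level",
    "variability_level",
    "tp_rank",
    "foreperiod_ms",
    "stimulus",
    "response",
    "rt_ms",
    "valid",
]


@dataclass
class GroupTruth:
    """Ground-truth group-level means for one cohort group.

    The boundary is parameterised as intercept + slope * x with
    x = 4 - tp_rank, so the intercept is the boundary at the highest level of
    temporal predictability.
    """

    b_intercept: float
    b_slope: float
    v: float
    t0: float
    v_slope: float = 0.0  # optional drift modulation over x (drift-varying truths)
    #: optional hazard sensitivity: the boundary shrinks by this fraction as
    #: the foreperiod moves from the bottom to the top of its condition's
    #: range, producing the classic foreperiod effect (faster late RTs)
    fp_hazard: float = 0.0
    sds: dict = field(default_factory=dict)

    def boundary_at(self, tp_rank: int) -> float:
        return self.b_intercept + self.b_slope * (4 - tp_rank)

    def drift_at(self, tp_rank: int) -> float:
        return self.v + self.v_slope * (4 - tp_rank)


@dataclass
class CohortSpec:
    groups: dict[str, GroupTruth]
    n_subjects_per_group: int = 16
    n_blocks: int = 4
    n_trials_per_block: int = 120
    lapse_rate: float = 0.0
    seed: int = 0
    dt: float = 5e-4
    t_max: float = 20.0

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must be in [0, 1)")
        for name, g in self.groups.items():
            if g.t0 <= 0:
                raise ValueError(f"group {name}: t0 must be positive")
            if not 0.0 <= g.fp_hazard < 1.0:
                raise ValueError(f"group {name}: fp_hazard must be in [0, 1)")
            for sd in g.sds.values():
                if sd < 0:
                    raise ValueError(f"group {name}: SDs must be non-negative")
            for rank in (1, 2, 3, 4):
                if g.boundary_at(rank) <= 0:
                    raise ValueError(
                        f"group {name}: implied boundary at tp_rank {rank} is "
                        f"{g.boundary_at(rank):.3f} <= 0"
                    )

    @classmethod
    def from_dict(cls, cfg: dict) -> "CohortSpec":
        groups = {
            name: GroupTruth(
                b_intercept=float(g["b_intercept"]),
                b_slope=float(g["b_slope"]),
                v=float(g["v"]),
                t0=float(g["t0"]),
                v_slope=float(g.get("v_slope", 0.0)),
                fp_hazard=float(g.get("fp_hazard", 0.0)),
                sds={k: float(s) for k, s in g.get("sds", {}).items()},
            )
            for name, g in cfg["groups"].items()
        }
        sim = cfg.get("simulation", {})
        return cls(
            groups=groups,
            n_subjects_per_group=int(cfg.get("n_subjects_per_group", 16)),
            n_blocks=int(cfg.get("n_blocks", 4)),
            n_trials_per_block=int(cfg.get("n_trials_per_block", 120)),
            lapse_rate=float(cfg.get("lapse_rate", 0.0)),
            seed=int(cfg.get("seed", 0)),
            dt=float(sim.get("dt", 5e-4)),
            t_max=float(sim.get("t_max", 20.0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_spec(**overrides) -> CohortSpec:
    """The packaged generative defaults (optionally overridden field-wise)."""
    text = importlib.resources.files("tempoprep").joinpath("defaults.yaml").read_text()
    spec = CohortSpec.from_dict(yaml.safe_load(text))
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise TypeError(f"unknown CohortSpec field {key!r}")
        setattr(spec, key, value)
    return spec


def _draw_subject_params(truth: GroupTruth, rng: np.random.Generator):
    """Subject-level draws around the group means; redraw until the implied
    boundary is positive at every predictability level and t0 > 0."""
    sds = truth.sds
    for _ in range(200):
        b0 = rng.normal(truth.b_intercept, sds.get("b_intercept", 0.0))
        b1 = rng.normal(truth.b_slope, sds.get("b_slope", 0.0))
        v = rng.normal(truth.v, sds.get("v", 0.0))
        v1 = rng.normal(truth.v_slope, sds.get("v_slope", 0.0))
        t0 = rng.normal(truth.t0, sds.get("t0", 0.0))
        if t0 > 0 and all(b0 + b1 * (4 - r) > 0.05 for r in (1, 2, 3, 4)):
            return b0, b1, v, v1, t0
    raise RuntimeError("could not draw valid subject parameters; check group means/SDs")


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the trial table and its ground-truth sidecar.

    Returns ``(trials, truth)``: trials has one row per trial in the declared
    CSV schema (times in float ms; integer rounding happens at file I/O), and
    truth has one row per (subject, parameter).  Reproducible bit-for-bit for
    a given spec and seed.
    """
    spec.validate()
    conditions = design.make_condition_grid()
    ss = np.random.SeedSequence(spec.seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    group_streams = ss.spawn(len(spec.groups))
    for (group, truth), gs in zip(spec.groups.items(), group_streams):
        # PD patients do one session on and one off medication; the off state
        # is recorded as session 2 of the same individuals.
        session = 2 if group.endswith("off") else 1
        prefix = "pd" if group.startswith("PD") else "ct"
        subj_streams = gs.spawn(spec.n_subjects_per_group)
        for s_idx, ssub in enumerate(subj_streams):
            rng = np.random.Generator(np.random.PCG64(ssub))
            subject_id = f"{prefix}{s_idx + 1:02d}"
            b0, b1, v, v1, t0 = _draw_subject_params(truth, rng)
            for pname, pval in (
                ("b_intercept", b0),
                ("b_slope", b1),
                ("v", v),
                ("v_slope", v1),
                ("t0", t0),
                *((f"b_tp{r}", b0 + b1 * (4 - r)) for r in (1, 2, 3, 4)),
                *((f"v_tp{r}", v + v1 * (4 - r)) for r in (1, 2, 3, 4)),
            ):
                truth_rows.append(
                    {"subject_id": subject_id, "group": group, "parameter": pname, "value": pval}
                )
            order_index = s_idx % 4  # Latin-square row, balanced over subjects
            schedule = design.build_session_schedule(
                conditions, spec.n_blocks, spec.n_trials_per_block, order_index, rng
            )
            b_trial = np.array(
                [
                    (b0 + b1 * (4 - c.tp_rank))
                    * (1.0 - truth.fp_hazard * (fp - c.lower) / (c.upper - c.lower))
                    for _, c, fp, _ in schedule
                ]
            )
            v_trial = np.array(
                [
                    (v + v1 * (4 - c.tp_rank)) * (1.0 if s == "RIGHT" else -1.0)
                    for _, c, _, s in schedule
                ]
            )
            sim_seed = int(rng.integers(2**31 - 1))
            rt_s, up, cens = simulate_trials(
                b_trial, v_trial, 0.5, t0, spec.dt, spec.t_max, sim_seed
            )
            lapse = rng.uniform(size=len(schedule)) < spec.lapse_rate
            for i, (block, cond, fp, stim) in enumerate(schedule):
                if lapse[i]:
                    response, rt_ms, valid = "NONE", np.nan, False
                else:
                    response = "RIGHT" if up[i] else "LEFT"
                    rt_ms = rt_s[i] * 1000.0
                    valid = not cens[i]
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "session": session,
                        "block": block,
                        "duration_level": cond.duration_level,
                        "variability_level": cond.variability_level,
                        "tp_rank": cond.tp_rank,
                        "foreperiod_ms": fp,
                        "stimulus": stim,
                        "response": response,
                        "rt_ms": rt_ms,
                        "valid": valid,
                    }
                )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "group", "parameter", "value"])
    return trials, truth
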