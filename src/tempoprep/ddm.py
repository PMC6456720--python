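"""Two-boundary drift-diffusion process under stimulus coding.

Scaling convention: the within-trial diffusion coefficient is fixed at 1 and
time is measured in seconds, so boundary separations land near 1 for human
two-choice reaction times.  The lower and upper boundaries map to LEFT and
RIGHT responses respectively (stimulus coding), and the drift is +v when the
stimulus calls for a RIGHT response and -v when it calls for LEFT, so a
single v measures evidence quality toward the correct boundary.
Milliseconds are converted to seconds at module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import (
    loglik_cell,
    simulate_fpt_batch,
    wfpt_logpdf,
)

__all__ = [
    "DDMParams",
    "FirstPassageSample",
    "upper_prob",
    "wfpt_density",
    "simulate_fpt",
    "loglik_trial",
    "loglik_trials",
]

LOG_ZERO = -np.inf  # sentinel for impossible data (rt <= t0)


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one subject/condition.

    b: boundary separation; v: drift rate per second; z: start point in
    (0, b); t0: non-decision time in seconds.
    """

    b: float
    v: float
    z: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("boundary separation b must be positive")
        if not 0 < self.z < self.b:
            raise ValueError("start point z must lie strictly inside (0, b)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be non-negative")
        if not math.isfinite(self.v):
            raise ValueError("drift rate v must be finite")

    @property
    def w(self) -> float:
        """Relative start point z/b."""
        return self.z / self.b


@dataclass(frozen=True)
class FirstPassageSample:
    boundary_hit: str  # "lower" | "upper"
    decision_time: float  # seconds
    rt: float  # seconds, includes t0
    censored: bool = False


def upper_prob(params: DDMParams) -> float:
    """Exact probability of absorption at the upper boundary.

    P(upper) = (1 - exp(-2 v z)) / (1 - exp(-2 v b)); continuous at v = 0
    where it equals z/b.  Evaluated via expm1 with an asymptotic branch for
    strongly negative drift to avoid overflow.
    """
    v, z, b = params.v, params.z, params.b
    if abs(v) < 1e-10:
        return params.z / params.b
    if -2.0 * v * b > 700.0:  # both expm1 terms overflow; use the log ratio
        return math.exp(2.0 * v * (b - z))
    return math.expm1(-2.0 * v * z) / math.expm1(-2.0 * v * b)


def wfpt_density(
    t: float, boundary: str, params: DDMParams, err_tol: float = 1e-7
) -> float:
    """Defective first-passage-time density at rt = t for the named boundary.

    ``t`` includes the non-decision time; for t <= t0 the density is 0 by
    contract.  The dual small-time/large-time series is truncated adaptively
    so the normalised-density error is below ``err_tol``.
    """
    if err_tol <= 0:
        raise ValueError("err_tol must be positive")
    if boundary not in ("lower", "upper"):
        raise ValueError("boundary must be 'lower' or 'upper'")
    td = t - params.t0
    if td <= 0:
        return 0.0
    lp = wfpt_logpdf(td, boundary == "upper", params.v, params.b, params.w, err_tol)
    return 0.0 if lp == LOG_ZERO else math.exp(lp)


def simulate_fpt(
    params: DDMParams,
    rng_or_seed,
    n: int = 1,
    dt: float = 1e-4,
    t_max: float = 20.0,
):
    """Euler-Maruyama first-passage samples (with bridge crossing correction).

    Returns a single :class:`FirstPassageSample` for n == 1, else a list.
    Walks that have not been absorbed by ``t_max`` are returned flagged
    censored, never dropped.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    seed = _as_seed(rng_or_seed)
    dec, up, cens = simulate_fpt_batch(n, params.b, params.v, params.w, dt, t_max, seed)
    samples = [
        FirstPassageSample(
            boundary_hit="upper" if u else "lower",
            decision_time=float(d),
            rt=float(d + params.t0),
            censored=bool(c),
        )
        for d, u, c in zip(dec, up, cens)
    ]
    return samples[0] if n == 1 else samples


def loglik_trial(
    rt: float, response: str, stimulus: str, params: DDMParams, err_tol: float = 1e-7
) -> float:
    """Log density of one trial under stimulus coding.

    LEFT responses are absorptions at the lower boundary, RIGHT at the upper;
    the drift is +v for RIGHT stimuli and -v for LEFT.  Returns -inf for
    rt <= t0 (impossible datum), never raises.
    """
    v_signed = params.v if stimulus == "RIGHT" else -params.v
    td = rt - params.t0
    if td <= 0:
        return LOG_ZERO
    return wfpt_logpdf(td, response == "RIGHT", v_signed, params.b, params.w, err_tol)


def loglik_trials(
    rt: np.ndarray,
    response_right: np.ndarray,
    stimulus_right: np.ndarray,
    params: DDMParams,
    err_tol: float = 1e-7,
) -> float:
    """Summed log likelihood of a trial set sharing one parameter vector.

    Vectorised entry point used by the hierarchical inference module; -inf
    if any trial is impossible under ``params``.
    """
    rt = np.ascontiguousarray(rt, dtype=np.float64)
    return float(
        loglik_cell(
            rt,
            np.ascontiguousarray(response_right, dtype=np.bool_),
            np.ascontiguousarray(stimulus_right, dtype=np.bool_),
            params.b,
            params.v,
            params.t0,
            params.w,
            err_tol,
        )
    )


def _as_seed(rng_or_seed) -> int:
    """Accept either an integer seed or a numpy Generator (a seed is drawn)."""
    if isinstance(rng_or_seed, np.random.Generator):
        return int(rng_or_seed.integers(2**31 - 1))
    return int(rng_or_seed)
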