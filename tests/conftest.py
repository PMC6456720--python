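import numpy as np
import pytest

from tempoprep import inference as inf
from tempoprep.cohort import CohortSpec, GroupTruth, generate_cohort
from tempoprep.stats import apply_rt_filter

DEFAULT_SDS = {"b_intercept": 0.1, "b_slope": 0.03, "v": 0.3, "t0": 0.01}


def small_cohort_spec(seed: int = 11, n_subjects: int = 4, n_trials: int = 60,
                      groups: dict | None = None) -> CohortSpec:
    groups = groups or {"G": GroupTruth(0.9, 0.05, 4.0, 0.25, sds=dict(DEFAULT_SDS))}
    return CohortSpec(
        groups=groups,
        n_subjects_per_group=n_subjects,
        n_blocks=4,
        n_trials_per_block=n_trials,
        seed=seed,
        dt=1e-3,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture(scope="session")
def small_cohort():
    """One-group cohort: 4 subjects x 240 trials, boundary-varying truth."""
    trials, truth = generate_cohort(small_cohort_spec())
    return apply_rt_filter(trials), truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A reduced M1 fit on the small cohort, shared across inference tests."""
    trials, truth = small_cohort
    model = inf.build_model("M1_boundary", trials)
    samples = inf.fit_mcmc(model, n_samples=3500, n_burn=1000, n_chains=2, seed=5)
    return model, samples, truth
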