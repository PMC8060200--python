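import numpy as np
import pytest

from trialwave import (
    GroupParams,
    RTSeries,
    Session,
    build_rt_series,
    decompose,
    frequency_grid,
    simulate_cohort,
    CohortSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def small_grid():
    return frequency_grid(32)


@pytest.fixture
def random_series(rng):
    return RTSeries(values=1200.0 + 100.0 * rng.standard_normal(32),
                    valid_mask=np.ones(32, dtype=bool))


@pytest.fixture
def clean_session(rng):
    """A 300-trial session with no missed trials."""
    return Session(subject_id="s0",
                   rts=1200.0 + 80.0 * rng.standard_normal(300))


def maps_for_cohort(sessions, f_max=0.5):
    T = sessions[0].n_trials
    grid = frequency_grid(T, f_max=f_max)
    return [decompose(build_rt_series(s), grid, subject_id=s.subject_id)
            for s in sessions]


@pytest.fixture
def null_cohort_maps():
    """Two small groups drawn from the same generative process (T=64)."""
    params = GroupParams(T=64, miss_prob=0.0)
    a, b = simulate_cohort(CohortSpec(n_a=6, n_b=6, params_a=params,
                                      params_b=params, seed=7))
    return maps_for_cohort(a), maps_for_cohort(b)
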