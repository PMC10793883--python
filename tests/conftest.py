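"""Shared fixtures: populations, trained runs, and hypothesis settings.

The multi-session closed-loop runs are expensive, so they are computed
once per test session and shared between the analysis and acceptance
tests.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import groupweight as gw

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")

LEARNING_SEEDS = (1, 2, 3, 4, 5)
N_SESSIONS = 12
SESSION_DURATION = 180.0
PRE_DURATION = 60.0


def run_training_with_seed(seed: int, schedule: gw.LearningSchedule):
    units = gw.make_population(rng=np.random.default_rng(seed))
    return gw.run_training(
        units,
        schedule,
        N_SESSIONS,
        gw.DecoderConfig(),
        gw.TaskConfig(),
        np.random.default_rng(seed + 1),
        session_duration=SESSION_DURATION,
        pre_experiment_duration=PRE_DURATION,
    )


@pytest.fixture(scope="session")
def learning_runs():
    """Five seeded 12-session runs under the default learning schedule."""
    return {seed: run_training_with_seed(seed, gw.LearningSchedule()) for seed in LEARNING_SEEDS}


@pytest.fixture(scope="session")
def null_runs():
    """Five seeded 12-session runs with learning switched off."""
    return {
        seed: run_training_with_seed(seed, gw.LearningSchedule.null())
        for seed in LEARNING_SEEDS
    }


@pytest.fixture(scope="session")
def short_log():
    """One short trained session log for format/analysis tests."""
    rng = np.random.default_rng(42)
    units = gw.make_population(rng=rng)
    # a few learning steps so the session has decent success and both outcomes
    sched = gw.LearningSchedule()
    for _ in range(6):
        units = gw.advance_learning(units, sched)
    groups = gw.population_group_spec(units)
    pre = gw.generate_idle_frame(units, 30.0, rng)
    mu, delta = gw.estimate_normalization(pre, groups, gw.DecoderConfig())
    log = gw.run_closed_loop_session(
        units,
        groups.with_normalization(mu, delta),
        gw.DecoderConfig(),
        gw.TaskConfig(),
        90.0,
        rng,
        engagement=0.85,
        session_index=1,
        seed=42,
    )
    log.pre_experiment = pre
    return log


@pytest.fixture
def rng():
    return np.random.default_rng(0)
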