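"""Shared fixtures: a small deterministic simulated contest.

The session-scoped dataset keeps the expensive simulation out of individual
tests; anything that mutates state must copy first.
"""

import pytest

from blinecrowd.pipeline import evaluate_contest
from blinecrowd.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_clips_training=40,
        n_clips_test=40,
        n_clips_unlabeled=40,
        n_users=60,
        opinions_per_user_mean=250.0,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_report(small_dataset):
    return evaluate_contest(
        small_dataset.opinions,
        small_dataset.clips,
        small_dataset.expert_table,
        seed=123,
        n_mc=200,
    )
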