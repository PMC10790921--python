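"""Shared fixtures: configs, degenerate operators, synthetic logs."""

import numpy as np
import pytest

from cybervigil import (
    OperatorParams,
    OutcomeRecord,
    TrialConfig,
    TrialLog,
    WorkloadSchedule,
)


@pytest.fixture
def static_config():
    return TrialConfig(schedule=WorkloadSchedule(mode="static"), seed=123)


@pytest.fixture
def dynamic_config():
    return TrialConfig(schedule=WorkloadSchedule(mode="dynamic"), seed=123)


@pytest.fixture
def short_static_config():
    # 10-min trial: same mechanics, ~6x cheaper than a full hour
    return TrialConfig(schedule=WorkloadSchedule(mode="static", duration=10.0), seed=77)


@pytest.fixture
def perfect_operator():
    """Detects everything, never guesses, reacts fast."""
    return OperatorParams(
        base_detect=(1.0, 1.0, 1.0),
        salience_coeff=0.0,
        load_coeff=0.0,
        rate_coeff=0.0,
        learn_coeff=0.0,
        fatigue_coeff=0.0,
        false_alarm_rate=(0.0, 0.0, 0.0),
        latency=(0.3, 0.05),
        center_service_time=(2.5, 0.05),
        prob_ceil=1.0,
    )


@pytest.fixture
def inert_operator():
    """Never detects a signal and never acts spontaneously."""
    return OperatorParams(
        base_detect=(0.0, 0.0, 0.0),
        salience_coeff=0.0,
        load_coeff=0.0,
        rate_coeff=0.0,
        learn_coeff=0.0,
        fatigue_coeff=0.0,
        false_alarm_rate=(0.0, 0.0, 0.0),
        prob_floor=0.0,
    )


def make_outcome_log(outcomes, mode="static", duration=60.0, seed=0):
    """A TrialLog with hand-written outcomes (for scoring tests)."""
    config = TrialConfig(schedule=WorkloadSchedule(mode=mode, duration=duration), seed=seed)
    recs = [OutcomeRecord(ts, screen, outcome, sig) for ts, screen, outcome, sig in outcomes]
    return TrialLog(config=config, operator_seed=None, stimuli=[], actions=[], outcomes=recs)


@pytest.fixture
def outcome_log_factory():
    return make_outcome_log


def random_outcome_log(rng, duration=60.0, n=400):
    """A log with uniformly random outcomes (property tests)."""
    screens = np.array(["left", "center", "right"])
    kinds = np.array(["hit", "miss", "false_alarm"])
    ts = np.sort(rng.uniform(0.0, duration * 60.0, size=n))
    rows = [
        (float(t), screens[rng.integers(3)], kinds[rng.integers(3)], None)
        for t in ts
    ]
    return make_outcome_log(rows, duration=duration)


@pytest.fixture
def random_log_factory():
    return random_outcome_log
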