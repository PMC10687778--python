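import numpy as np
import pytest

from batbandit import ModelSpec, Session, make_schedule, simulate_agent


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)


@pytest.fixture
def tiny_session():
    """Three trials: chose feeder 0 twice (win then loss), then feeder 1."""
    return Session(bat_id="b1", night=1, environment="stable",
                   actions=[0, 0, 1], rewards=[1, 0, 0])


def random_sessions(rng, n_nights=2, n_trials=40, bat_id="b"):
    """Sessions with uniformly random choices/rewards (no model structure)."""
    return [
        Session(bat_id=bat_id, night=k + 1, environment="stable",
                actions=rng.integers(0, 2, n_trials),
                rewards=rng.integers(0, 2, n_trials))
        for k in range(n_nights)
    ]


@pytest.fixture
def rl_session_2000():
    """One long stable-schedule session from a known Q-learner."""
    schedule = make_schedule("stable", 2000)
    return simulate_agent(ModelSpec("rl", "reset"), {"alpha": 0.3, "beta": 4.0},
                          schedule, seed=424242)
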