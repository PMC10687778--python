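"""Reward schedules, agent simulation, and optimality analyses.

Two schedule regimes mirror the experimental environments:

* stable — one feeder pays with probability 0.8 and the other with 0.2,
  held for a block of 251 trials, then reversed for 214 trials, alternating
  until the requested length (the block lengths are the empirical trial
  counts before/after the mid-experiment reversal);
* volatile — the probabilities reverse every 13 trials (the empirical
  number of trials per hour, standing in for the hourly reversal).

Softmax Q-learning agents and stochastic Win-Stay-Lose-Shift agents are
simulated against these schedules to locate the learning rate (or WSLS
parameter pair) that maximises foraging success, and observed success rates
are compared against simulated distributions with a two-tailed 5% empirical
percentile rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .models import ModelSpec, Session, WSLSParams

__all__ = [
    "EnvironmentSchedule",
    "GridResult",
    "WSLSGridResult",
    "PercentileTestResult",
    "make_schedule",
    "simulate_agent",
    "grid_search_alpha",
    "wsls_grid",
    "wsls_expected_success",
    "percentile_test",
    "default_beta_sample",
]

P_HIGH = 0.8
P_LOW = 0.2
STABLE_BLOCKS = (251, 214)
VOLATILE_PERIOD = 13

#: Range of the default inverse-temperature distribution used when no
#: empirical beta values are supplied (betas are drawn uniformly from it).
DEFAULT_BETA_RANGE = (1.0, 7.0)


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Per-trial reward-probability pairs for the two feeders."""

    env: str
    p_feeder: np.ndarray          # shape (n_trials, 2)
    reversal_points: np.ndarray   # 0-based indices of first trial of each new block

    @property
    def n_trials(self) -> int:
        return int(self.p_feeder.shape[0])


def make_schedule(env: str, n_trials: int, *, p_high: float = P_HIGH,
                  p_low: float = P_LOW, stable_blocks: Sequence[int] = STABLE_BLOCKS,
                  volatile_period: int = VOLATILE_PERIOD,
                  start_good: int = 0) -> EnvironmentSchedule:
    """Build the reward schedule for one environment.

    ``start_good`` is the feeder holding the high probability on trial 0.
    The final partial block is truncated at ``n_trials``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if env not in ("stable", "volatile"):
        raise ValueError(f"unknown environment {env!r}; expected 'stable' or 'volatile'")
    if start_good not in (0, 1):
        raise ValueError("start_good must be 0 or 1")
    if env == "volatile":
        block_iter = iter(lambda: volatile_period, None)
    else:
        cyc = list(stable_blocks)

        def _blocks():
            i = 0
            while True:
                yield cyc[i % len(cyc)]
                i += 1

        block_iter = _blocks()

    good = np.empty(n_trials, dtype=np.int8)
    reversals = []
    t = 0
    current = start_good
    for length in block_iter:
        end = min(t + length, n_trials)
        good[t:end] = current
        t = end
        if t >= n_trials:
            break
        reversals.append(t)
        current = 1 - current
    p = np.where(good[:, None] == np.arange(2)[None, :], p_high, p_low)
    return EnvironmentSchedule(env=env, p_feeder=p,
                               reversal_points=np.asarray(reversals, dtype=int))


def _simulate_rl_batch(alphas: np.ndarray, betas: np.ndarray,
                       schedule: EnvironmentSchedule,
                       u_choice: np.ndarray, u_reward: np.ndarray):
    """Vectorised batch of Q-learning agents sharing one schedule.

    ``u_choice``/``u_reward`` hold pre-drawn uniforms, shape (n_agents,
    n_trials), so each agent consumes its own reproducible stream.
    Returns (actions, rewards) as (n_agents, n_trials) int8 arrays.
    """
    n_agents = alphas.size
    n = schedule.n_trials
    sched = schedule.p_feeder
    q0 = np.zeros(n_agents)
    q1 = np.zeros(n_agents)
    actions = np.empty((n_agents, n), dtype=np.int8)
    rewards = np.empty((n_agents, n), dtype=np.int8)
    for t in range(n):
        p0 = expit(betas * (q0 - q1))
        a = (u_choice[:, t] >= p0).astype(np.int8)
        p_r = np.where(a == 0, sched[t, 0], sched[t, 1])
        r = (u_reward[:, t] < p_r).astype(np.int8)
        chose0 = a == 0
        q0 = np.where(chose0, q0 + alphas * (r - q0), q0)
        q1 = np.where(chose0, q1, q1 + alphas * (r - q1))
        actions[:, t] = a
        rewards[:, t] = r
    return actions, rewards


def _simulate_wsls_batch(p_stay: float, p_shift: float,
                         schedule: EnvironmentSchedule,
                         u_choice: np.ndarray, u_reward: np.ndarray):
    """Vectorised batch of WSLS agents (first trial is a fair coin flip)."""
    n_sims, n = u_choice.shape
    sched = schedule.p_feeder
    actions = np.empty((n_sims, n), dtype=np.int8)
    rewards = np.empty((n_sims, n), dtype=np.int8)
    a = (u_choice[:, 0] >= 0.5).astype(np.int8)
    for t in range(n):
        if t > 0:
            p_same = np.where(rewards[:, t - 1] == 1, p_stay, 1.0 - p_shift)
            same = u_choice[:, t] < p_same
            a = np.where(same, actions[:, t - 1], 1 - actions[:, t - 1]).astype(np.int8)
        p_r = np.where(a == 0, sched[t, 0], sched[t, 1])
        rewards[:, t] = u_reward[:, t] < p_r
        actions[:, t] = a
    return actions, rewards


def simulate_agent(spec: ModelSpec, params, schedule: EnvironmentSchedule,
                   seed: int | None = None, bat_id: str = "sim",
                   night: int = 1) -> Session:
    """Simulate one agent across a schedule: choose, draw reward, update.

    No between-night forgetting is simulated (the schedule is one continuous
    run).  Supports the plain Q-learner and WSLS; the perseveration model is
    deliberately not simulated.
    """
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    u_choice = rng.random((1, n))
    u_reward = rng.random((1, n))
    if spec.family == "rl":
        p = params.as_dict() if hasattr(params, "as_dict") else dict(params)
        actions, rewards = _simulate_rl_batch(
            np.array([p["alpha"]]), np.array([p["beta"]]), schedule,
            u_choice, u_reward)
    elif spec.family == "wsls":
        p = params.as_dict() if hasattr(params, "as_dict") else dict(params)
        actions, rewards = _simulate_wsls_batch(
            p["p_stay"], p["p_shift"], schedule, u_choice, u_reward)
    else:
        raise ValueError(f"simulation is not defined for family {spec.family!r}")
    return Session(bat_id=bat_id, night=night, environment=schedule.env,
                   actions=actions[0], rewards=rewards[0])


def default_beta_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """Default inverse-temperature draw when no empirical betas are given."""
    lo, hi = DEFAULT_BETA_RANGE
    return rng.uniform(lo, hi, n)


@dataclass
class GridResult:
    """Success-rate curve over a learning-rate grid."""

    env: str
    grid: np.ndarray
    mean_success: np.ndarray
    sd_success: np.ndarray
    per_agent_success: np.ndarray  # shape (len(grid), n_agents)
    betas: np.ndarray
    n_agents: int
    n_trials: int
    seed: int | None

    @property
    def best_alpha(self) -> float:
        return float(self.grid[int(np.argmax(self.mean_success))])


def _agent_uniforms(seed: int | None, agent_index: int,
                    n_trials: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent stream keyed on the agent index alone.

    The same stream is reused at every grid point (common random numbers),
    which pairs the success estimates across learning rates and sharpens
    the grid comparison; growing the agent count never reshuffles earlier
    agents' streams.
    """
    ss = np.random.SeedSequence(0 if seed is None else seed,
                                spawn_key=(agent_index,))
    rng = np.random.default_rng(ss)
    return rng.random(n_trials), rng.random(n_trials)


def grid_search_alpha(env: str, betas: Sequence[float] | None = None,
                      n_agents: int = 108, n_trials: int = 2000,
                      grid: Sequence[float] | None = None,
                      seed: int | None = None) -> GridResult:
    """Mean simulated success per learning rate over an alpha grid.

    Each grid point simulates ``n_agents`` Q-learning agents for
    ``n_trials`` trials.  ``betas`` is cycled over the agents (as when a
    set of per-animal empirical values is reused several times each);
    when absent, betas are drawn from the default uniform distribution.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    schedule = make_schedule(env, n_trials)
    if betas is None:
        beta_rng = np.random.default_rng(
            np.random.SeedSequence(0 if seed is None else seed, spawn_key=(999_983,)))
        betas = default_beta_sample(n_agents, beta_rng)
    betas = np.asarray(
        [betas[i % len(betas)] for i in range(n_agents)], dtype=float)

    uc = np.empty((n_agents, n_trials))
    ur = np.empty((n_agents, n_trials))
    for j in range(n_agents):
        uc[j], ur[j] = _agent_uniforms(seed, j, n_trials)
    success = np.empty((grid.size, n_agents))
    for gi, alpha in enumerate(grid):
        _, rewards = _simulate_rl_batch(np.full(n_agents, alpha), betas,
                                        schedule, uc, ur)
        success[gi] = rewards.mean(axis=1)
    return GridResult(env=env, grid=grid, mean_success=success.mean(axis=1),
                      sd_success=success.std(axis=1, ddof=1),
                      per_agent_success=success, betas=betas,
                      n_agents=n_agents, n_trials=n_trials, seed=seed)


@dataclass
class WSLSGridResult:
    """Success-rate surface over the (p_stay, p_shift) grid."""

    env: str
    p_stay_grid: np.ndarray
    p_shift_grid: np.ndarray
    mean_success: np.ndarray       # shape (len(p_stay), len(p_shift))
    sd_success: np.ndarray
    per_sim_success: np.ndarray    # shape (len(p_stay), len(p_shift), n_sims)
    n_sims: int
    n_trials: int
    seed: int | None


def wsls_grid(env: str, grid: Sequence[float] | None = None, n_sims: int = 100,
              n_trials: int = 2000, seed: int | None = None) -> WSLSGridResult:
    """Mean success of WSLS agents across the (p_stay, p_shift) grid.

    Every cell runs ``n_sims`` simulations of ``n_trials`` trials against
    the environment's schedule and averages the success rate.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    schedule = make_schedule(env, n_trials)
    m = grid.size
    success = np.empty((m, m, n_sims))
    for i, p_stay in enumerate(grid):
        for j, p_shift in enumerate(grid):
            rng = np.random.default_rng(
                np.random.SeedSequence(0 if seed is None else seed, spawn_key=(i, j)))
            uc = rng.random((n_sims, n_trials))
            ur = rng.random((n_sims, n_trials))
            _, rewards = _simulate_wsls_batch(p_stay, p_shift, schedule, uc, ur)
            success[i, j] = rewards.mean(axis=1)
    return WSLSGridResult(env=env, p_stay_grid=grid, p_shift_grid=grid,
                          mean_success=success.mean(axis=2),
                          sd_success=success.std(axis=2, ddof=1),
                          per_sim_success=success, n_sims=n_sims,
                          n_trials=n_trials, seed=seed)


def wsls_expected_success(schedule: EnvironmentSchedule, p_stay: float,
                          p_shift: float, p_first: float = 0.5) -> float:
    """Exact expected success of a WSLS agent on a schedule (no Monte Carlo).

    The agent's state is fully summarised by the marginal probability f_t of
    sitting on feeder 0, which obeys a linear recursion: after choosing a
    feeder with reward probability p, the agent repeats it with probability
    p*p_stay + (1-p)*(1-p_shift).  Iterating this recursion over the
    schedule and averaging the per-trial success probabilities gives the
    exact expectation, independent of the stochastic simulator.
    """
    sched = schedule.p_feeder
    f = p_first  # P(choice = feeder 0)
    total = 0.0
    for t in range(schedule.n_trials):
        p0, p1 = sched[t]
        total += f * p0 + (1.0 - f) * p1
        stay0 = p0 * p_stay + (1.0 - p0) * (1.0 - p_shift)
        stay1 = p1 * p_stay + (1.0 - p1) * (1.0 - p_shift)
        f = f * stay0 + (1.0 - f) * (1.0 - stay1)
    return total / schedule.n_trials


@dataclass(frozen=True)
class PercentileTestResult:
    """Empirical two-tailed percentile comparison of one observation."""

    tail: str          # "low", "high", or "ns"
    rank_low: int      # 1 + number of simulations strictly below the observation
    rank_high: int     # 1 + number strictly above
    n_simulations: int
    tail_fraction: float

    @property
    def significant(self) -> bool:
        return self.tail != "ns"


def percentile_test(observed_success: float, simulated_successes: Sequence[float],
                    tail_fraction: float = 0.05) -> PercentileTestResult:
    """Is the observation in the lowest or highest ``tail_fraction`` of sims?

    The rule is strict: the observation is flagged only when its rank from
    the relevant end does not exceed ``tail_fraction * n``.
    """
    sims = np.asarray(simulated_successes, dtype=float)
    if sims.size == 0:
        raise ValueError("simulated_successes must not be empty")
    if sims.size < 20:
        raise ValueError("need at least 20 simulated values for a 5% tail rule")
    n = sims.size
    rank_low = 1 + int((sims < observed_success).sum())
    rank_high = 1 + int((sims > observed_success).sum())
    cutoff = tail_fraction * n
    if rank_low <= cutoff:
        tail = "low"
    elif rank_high <= cutoff:
        tail = "high"
    else:
        tail = "ns"
    return PercentileTestResult(tail=tail, rank_low=rank_low, rank_high=rank_high,
                                n_simulations=n, tail_fraction=tail_fraction)
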