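"""Synthetic cohorts with the study's structure and known ground truth.

The generator emulates the experimental design: two groups of bats (15 in a
stable environment, 10 in a volatile one), four nights per bat, a trial
count per night drawn from a truncated normal with mean 120.3 and SD 59.2
(floored at 20 so per-night fits stay defined), and feeder reward
probabilities 0.8/0.2.  In the stable environment the rewarding side is
fixed for nights 1-2 and reversed for nights 3-4; in the volatile
environment it reverses every 13 trials (the empirical trials-per-hour
equivalent of the hourly switch).

Choices are generated by a configurable agent — by default a softmax
Q-learner whose Q-values decay between nights (the best-fitting model
class) — and every latent parameter is recorded so fits can be validated
against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import fit_model
from .models import ModelSpec, Session
from .simulation import make_schedule

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_param_sampler",
    "generate_cohort",
    "generate_landing_log",
    "recovery_experiment",
    "summarize_recovery",
]

from .metrics import LandingEvent

#: Per-environment defaults for the true-parameter distributions, chosen to
#: match the group-level means/SDs reported for fitted animals: learning
#: rate 0.22+/-0.28 (stable) vs 0.14+/-0.17 (volatile); overnight decay
#: 0.33+/-0.42 vs 0.55+/-0.41.  Betas are uniform on [1, 7].
DEFAULT_ALPHA_DIST = {"stable": (0.22, 0.28), "volatile": (0.14, 0.17)}
DEFAULT_DECAY_DIST = {"stable": (0.33, 0.42), "volatile": (0.55, 0.41)}
DEFAULT_BETA_RANGE = (1.0, 7.0)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def default_param_sampler(rng: np.random.Generator, environment: str,
                          bat_index: int) -> dict[str, float]:
    """True-parameter draw for one bat of the default (decaying Q-learner)
    cohort."""
    a_mean, a_sd = DEFAULT_ALPHA_DIST[environment]
    d_mean, d_sd = DEFAULT_DECAY_DIST[environment]
    return {
        "alpha": float(_truncnorm(rng, a_mean, a_sd, 0.0, 1.0)),
        "beta": float(rng.uniform(*DEFAULT_BETA_RANGE)),
        "decay": float(_truncnorm(rng, d_mean, d_sd, 0.0, 1.0)),
    }


@dataclass
class CohortConfig:
    """Shape and ground-truth distributions of a synthetic cohort."""

    n_stable: int = 15
    n_volatile: int = 10
    n_nights: int = 4
    trials_mean: float = 120.3
    trials_sd: float = 59.2
    trials_min: int = 20
    trials_fixed: int | None = None   # overrides the distribution when set
    model: ModelSpec = field(default_factory=lambda: ModelSpec("rl", "decay"))
    param_sampler: Callable[[np.random.Generator, str, int], dict] | None = None
    volatile_period: int = 13
    p_high: float = 0.8
    p_low: float = 0.2
    mean_gap_s: float = 30.0

    def __post_init__(self) -> None:
        if min(self.n_stable + self.n_volatile, self.n_nights) < 1:
            raise ValueError("cohort must contain at least one bat and one night")
        if self.trials_min < 1 or self.trials_sd < 0:
            raise ValueError("invalid trials-per-night distribution")


@dataclass
class GroundTruth:
    """Latent parameters and design facts behind one synthetic cohort."""

    seed: int | None
    model: str
    bats: list[dict]

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bats:
            row = {"bat_id": b["bat_id"], "environment": b["environment"]}
            row.update(b["params"])
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        return json.dumps({"seed": self.seed, "model": self.model,
                           "bats": self.bats}, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(seed=d["seed"], model=d["model"], bats=d["bats"])


def _simulate_rl_night(alpha: float, beta: float, q: list[float],
                       schedule, rng: np.random.Generator):
    n = schedule.n_trials
    sched = schedule.p_feeder
    u_choice = rng.random(n)
    u_reward = rng.random(n)
    actions = np.empty(n, dtype=np.int8)
    rewards = np.empty(n, dtype=np.int8)
    q0, q1 = q
    for t in range(n):
        x = beta * (q0 - q1)
        p0 = 1.0 / (1.0 + np.exp(-x))
        a = 0 if u_choice[t] < p0 else 1
        r = 1 if u_reward[t] < sched[t, a] else 0
        if a == 0:
            q0 += alpha * (r - q0)
        else:
            q1 += alpha * (r - q1)
        actions[t] = a
        rewards[t] = r
    return actions, rewards, [q0, q1]


def _simulate_wsls_night(p_stay: float, p_shift: float, schedule,
                         rng: np.random.Generator):
    n = schedule.n_trials
    sched = schedule.p_feeder
    u_choice = rng.random(n)
    u_reward = rng.random(n)
    actions = np.empty(n, dtype=np.int8)
    rewards = np.empty(n, dtype=np.int8)
    for t in range(n):
        if t == 0:
            a = 0 if u_choice[t] < 0.5 else 1
        else:
            p_same = p_stay if rewards[t - 1] == 1 else 1.0 - p_shift
            a = actions[t - 1] if u_choice[t] < p_same else 1 - actions[t - 1]
        rewards[t] = 1 if u_reward[t] < sched[t, a] else 0
        actions[t] = a
    return actions, rewards


def _night_schedule(cfg: CohortConfig, environment: str, night: int,
                    n_trials: int, good_side_night1: int):
    if environment == "stable":
        side = good_side_night1 if night <= cfg.n_nights // 2 else 1 - good_side_night1
        return make_schedule("stable", n_trials, p_high=cfg.p_high, p_low=cfg.p_low,
                             stable_blocks=(n_trials,), start_good=side)
    return make_schedule("volatile", n_trials, p_high=cfg.p_high, p_low=cfg.p_low,
                         volatile_period=cfg.volatile_period,
                         start_good=good_side_night1)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full cohort's trial log plus its ground truth.

    The returned frame follows the package's trial-log schema (``bat_id``,
    ``environment``, ``night``, ``trial_index``, ``time_s``, ``feeder``,
    ``reward``) and is fully deterministic given ``seed``.
    """
    cfg = config or CohortConfig()
    sampler = cfg.param_sampler or default_param_sampler
    if sampler is default_param_sampler and cfg.model.name != "rl/decay":
        raise ValueError("the default parameter sampler only covers the "
                         "decaying Q-learner; supply param_sampler for "
                         f"model {cfg.model.name!r}")
    envs = ["stable"] * cfg.n_stable + ["volatile"] * cfg.n_volatile
    rows = []
    bats = []
    for bi, env in enumerate(envs):
        rng = np.random.default_rng(
            np.random.SeedSequence(0 if seed is None else seed, spawn_key=(bi,)))
        bat_id = f"{env}{bi + 1:02d}"
        params = sampler(rng, env, bi)
        good_side = int(rng.integers(0, 2))
        if cfg.trials_fixed is not None:
            trials_per_night = [cfg.trials_fixed] * cfg.n_nights
        else:
            trials_per_night = [
                int(round(_truncnorm(rng, cfg.trials_mean, cfg.trials_sd,
                                     cfg.trials_min, np.inf)))
                for _ in range(cfg.n_nights)
            ]
        q = [0.0, 0.0]
        for night in range(1, cfg.n_nights + 1):
            n = trials_per_night[night - 1]
            schedule = _night_schedule(cfg, env, night, n, good_side)
            if cfg.model.family == "wsls":
                actions, rewards = _simulate_wsls_night(
                    params["p_stay"], params["p_shift"], schedule, rng)
            else:
                if night > 1:
                    if cfg.model.carryover == "reset":
                        q = [0.0, 0.0]
                    elif cfg.model.carryover == "decay":
                        f = (1.0 - params["decay"]
                             if cfg.model.decay_convention == "forget"
                             else params["decay"])
                        q = [f * q[0], f * q[1]]
                actions, rewards, q = _simulate_rl_night(
                    params["alpha"], params["beta"], q, schedule, rng)
            times = np.cumsum(rng.exponential(cfg.mean_gap_s, n))
            for t in range(n):
                rows.append((bat_id, env, night, t + 1, round(float(times[t]), 3),
                             int(actions[t]), int(rewards[t])))
        bats.append({"bat_id": bat_id, "environment": env, "params": params,
                     "good_side_night1": good_side,
                     "trials_per_night": trials_per_night})
    frame = pd.DataFrame(rows, columns=["bat_id", "environment", "night",
                                        "trial_index", "time_s", "feeder", "reward"])
    truth = GroundTruth(seed=seed, model=cfg.model.name, bats=bats)
    return frame, truth


def generate_landing_log(session: Session, *, mean_gap_s: float = 30.0,
                         dwell_mean_s: float = 5.0, injection_rate: float = 0.0,
                         seed: int | None = None) -> list[LandingEvent]:
    """Expand a session's trials into a raw landing/leaving log.

    Inter-trial gaps are exponential on top of a fixed offset large enough
    that every real trial clears the 3-second re-landing rule even when
    fast same-feeder re-landings are injected between trials.
    ``injection_rate`` controls the fraction of trials followed by one
    injected sub-3-second re-landing (merged away by trial extraction).
    """
    rng = np.random.default_rng(seed)
    n = session.n_trials
    events: list[LandingEvent] = []
    n_inject = int(round(injection_rate * n))
    inject_at = set(rng.choice(n, size=n_inject, replace=False)) if n_inject else set()
    t = float(rng.exponential(mean_gap_s))
    for i in range(n):
        dwell = 0.5 + float(rng.exponential(dwell_mean_s))
        feeder = int(session.actions[i])
        reward = int(session.rewards[i])
        events.append(LandingEvent(feeder=feeder, land_time_s=round(t, 3),
                                   leave_time_s=round(t + dwell, 3), reward=reward))
        leave = t + dwell
        if i in inject_at:
            # quick same-feeder re-landing inside the 3 s merge window
            rl_land = leave + float(rng.uniform(0.1, 2.0))
            events.append(LandingEvent(feeder=feeder, land_time_s=round(rl_land, 3),
                                       leave_time_s=round(rl_land + 0.3, 3),
                                       reward=reward))
            leave = rl_land + 0.3
        # 6 s offset: >= 3 s after the original leave AND after any injected
        # re-landing's leave, so the next trial is never merged
        t = leave + 6.0 + float(rng.exponential(mean_gap_s))
    return events


def recovery_experiment(config: CohortConfig, spec: ModelSpec | None = None,
                        n_replicates: int = 1, seed: int | None = None,
                        n_starts: int = 10) -> pd.DataFrame:
    """Generate cohorts, refit them, and tabulate true vs recovered values.

    Returns a long frame with one row per (replicate, bat, parameter):
    columns ``replicate``, ``bat_id``, ``environment``, ``param``, ``true``,
    ``fitted``.  Summarise with :func:`summarize_recovery`.
    """
    spec = spec or config.model
    rows = []
    for rep in range(n_replicates):
        rep_seed = None if seed is None else int(
            np.random.SeedSequence(seed, spawn_key=(rep,)).generate_state(1)[0] % (2**31))
        frame, truth = generate_cohort(config, seed=rep_seed)
        sessions_by_bat = _sessions_from_frame(frame)
        for bat in truth.bats:
            fit = fit_model(sessions_by_bat[bat["bat_id"]], spec,
                            n_starts=n_starts, seed=rep_seed)
            for name in spec.param_names:
                if name not in bat["params"]:
                    continue
                rows.append({"replicate": rep, "bat_id": bat["bat_id"],
                             "environment": bat["environment"], "param": name,
                             "true": bat["params"][name],
                             "fitted": fit.params[name]})
    return pd.DataFrame(rows)


def summarize_recovery(recovery: pd.DataFrame) -> pd.DataFrame:
    """Bias, RMSE and true-vs-fitted Pearson r per parameter."""
    out = []
    for param, g in recovery.groupby("param"):
        err = g["fitted"] - g["true"]
        r = np.nan
        if g["true"].nunique() > 1 and g["fitted"].nunique() > 1:
            r = float(stats.pearsonr(g["true"], g["fitted"])[0])
        out.append({"param": param, "n": len(g), "bias": float(err.mean()),
                    "rmse": float(np.sqrt((err ** 2).mean())), "pearson_r": r})
    return pd.DataFrame(out)


def _sessions_from_frame(frame: pd.DataFrame) -> dict[str, list[Session]]:
    from .io import sessions_from_frame
    by_bat: dict[str, list[Session]] = {}
    for s in sessions_from_frame(frame):
        by_bat.setdefault(s.bat_id, []).append(s)
    return by_bat
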