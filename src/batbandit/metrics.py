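"""Descriptive behavioural statistics: trial extraction, success rate,
stay probabilities, the reward effect, QC filters, and the night-trend test.

A "trial" is a landing on a feeder — counted either when the animal
switches feeders, or when it re-lands on the same feeder at least three
seconds after last leaving it.  Quicker same-feeder re-landings are merged
into the original trial.

The reward effect is the increase in stay probability caused by reward:
P(stay | previous trial rewarded) - P(stay | previous trial unrewarded),
where staying means choosing the same feeder on two consecutive trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ChoiceTrial, Session

__all__ = [
    "LandingEvent",
    "BehaviorSummary",
    "extract_trials",
    "success_rate",
    "reward_effect",
    "qc_filter",
    "reward_effect_trend",
]

#: Minimum time (s) since leaving a feeder for a same-feeder re-landing to
#: count as a new trial.  The threshold is inclusive.
MIN_RELANDING_GAP_S = 3.0


@dataclass(frozen=True)
class LandingEvent:
    """One landing on a feeder, with its landing/leaving times and payout."""

    feeder: int
    land_time_s: float
    leave_time_s: float
    reward: int

    def __post_init__(self) -> None:
        if self.feeder not in (0, 1):
            raise ValueError("feeder must be 0 or 1")
        if self.reward not in (0, 1):
            raise ValueError("reward must be 0 or 1")
        if self.leave_time_s < self.land_time_s:
            raise ValueError("leave time precedes land time")
        if self.land_time_s < 0:
            raise ValueError("times must be non-negative")


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-session descriptive statistics."""

    success_rate: float
    p_stay_given_reward: float | None
    p_stay_given_no_reward: float | None
    reward_effect: float | None
    n_trials: int


def extract_trials(log: Sequence[LandingEvent],
                   min_gap_s: float = MIN_RELANDING_GAP_S) -> list[ChoiceTrial]:
    """Collapse a raw landing log into decision trials.

    A landing opens a new trial when the feeder differs from the previous
    landing's feeder, or when at least ``min_gap_s`` seconds have passed
    since the animal last left this same feeder.  Sub-threshold same-feeder
    re-landings extend the existing trial (keeping its original reward).
    """
    trials: list[ChoiceTrial] = []
    last_leave: dict[int, float] = {}
    prev_feeder: int | None = None
    prev_land = -np.inf
    for ev in log:
        if ev.land_time_s < prev_land:
            raise ValueError("landing log is not ordered by landing time")
        if prev_feeder is not None and ev.land_time_s < last_leave.get(prev_feeder, -np.inf) \
                and ev.feeder != prev_feeder:
            raise ValueError("overlapping landing intervals in log")
        is_new = (
            prev_feeder is None
            or ev.feeder != prev_feeder
            or ev.land_time_s - last_leave[ev.feeder] >= min_gap_s
        )
        if is_new:
            trials.append(ChoiceTrial(index=len(trials) + 1, action=ev.feeder,
                                      reward=ev.reward, time_s=ev.land_time_s))
        last_leave[ev.feeder] = ev.leave_time_s
        prev_feeder = ev.feeder
        prev_land = ev.land_time_s
    return trials


def _rewards_actions(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, Session):
        return np.asarray(trials.rewards), np.asarray(trials.actions)
    rewards = np.array([t.reward for t in trials], dtype=int)
    actions = np.array([t.action for t in trials], dtype=int)
    return rewards, actions


def success_rate(trials) -> float:
    """Fraction of trials that paid out a reward."""
    rewards, _ = _rewards_actions(trials)
    if rewards.size == 0:
        raise ValueError("success rate of zero trials is undefined")
    return float(rewards.mean())


def reward_effect(trials) -> BehaviorSummary:
    """Stay probabilities conditioned on the previous reward and their gap.

    Transitions are consecutive trial pairs within the given sequence (no
    cross-night pairs should be passed in).  If one of the two conditions
    has no observations, its probability and the effect are reported as
    None rather than a number.
    """
    rewards, actions = _rewards_actions(trials)
    if rewards.size < 2:
        raise ValueError("need at least 2 trials to define staying")
    stayed = actions[1:] == actions[:-1]
    prev_rewarded = rewards[:-1] == 1

    def _cond(mask: np.ndarray) -> float | None:
        return float(stayed[mask].mean()) if mask.any() else None

    p_r = _cond(prev_rewarded)
    p_nr = _cond(~prev_rewarded)
    effect = None if (p_r is None or p_nr is None) else p_r - p_nr
    return BehaviorSummary(success_rate=float(rewards.mean()),
                           p_stay_given_reward=p_r, p_stay_given_no_reward=p_nr,
                           reward_effect=effect, n_trials=int(rewards.size))


def qc_filter(summaries: pd.DataFrame, *, n_nights: int = 4,
              negative_night_threshold: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study's exclusion rules to per-bat, per-night summaries.

    Expects columns ``bat_id``, ``night``, ``reward_effect`` and optionally
    a boolean ``hardware_failure``.  Rules:

    * a night flagged as hardware failure is dropped together with all
      subsequent nights of that bat;
    * a bat whose reward effect is negative on at least
      ``negative_night_threshold`` of its ``n_nights`` nights is dropped
      entirely (it failed to learn);

    Returns the filtered frame and an exclusion report (bat, night, reason).
    """
    df = summaries.copy()
    exclusions: list[dict] = []

    if "hardware_failure" in df.columns:
        for bat_id, group in df.groupby("bat_id"):
            failed = group.loc[group["hardware_failure"].astype(bool), "night"]
            if not failed.empty:
                first_bad = int(failed.min())
                dropped = group.loc[group["night"] >= first_bad]
                for night in sorted(dropped["night"]):
                    exclusions.append({
                        "bat_id": bat_id, "night": int(night),
                        "reason": ("hardware failure" if night == first_bad
                                   else f"follows hardware failure on night {first_bad}"),
                    })
                df = df.drop(dropped.index)

    for bat_id, group in df.groupby("bat_id"):
        effects = group["reward_effect"].astype(float)
        if (effects < 0).sum() >= negative_night_threshold:
            for night in sorted(group["night"]):
                exclusions.append({
                    "bat_id": bat_id, "night": int(night),
                    "reason": (f"negative reward effect on >= "
                               f"{negative_night_threshold} of {n_nights} nights"),
                })
            df = df.drop(group.index)

    report = pd.DataFrame(exclusions, columns=["bat_id", "night", "reason"])
    return df.reset_index(drop=True), report


def reward_effect_trend(median_effects: Sequence[float],
                        nights: Sequence[int] = (1, 2, 3, 4)) -> tuple[float, float]:
    """Pearson correlation of the median reward effect with night number."""
    y = np.asarray(median_effects, dtype=float)
    x = np.asarray(nights, dtype=float)
    if y.size != x.size:
        raise ValueError("one median per night required")
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
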