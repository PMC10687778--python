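"""Decision models for two-armed-bandit foraging: Q-learning and WSLS.

This module contains the trial-level likelihood machinery shared by the
fitting and simulation layers.  Three model families are supported:

``rl``
    Softmax Q-learning with learning rate ``alpha`` and inverse temperature
    ``beta``.  After each trial the chosen action's value moves toward the
    observed reward by a fraction ``alpha`` of the prediction error; the
    unchosen value is left untouched.

``rl_perseveration``
    The same Q-learner augmented with a choice-perseveration trace
    ``p_val`` per action (initialised at 0.5, pushed toward 1 for the chosen
    action and toward 0 for the unchosen one at rate ``p_rate``, regardless
    of reward), entering the softmax with weight ``p_exp``.  Setting
    ``p_exp = 0`` reduces exactly to the plain Q-learner.

``wsls``
    A stochastic Win-Stay-Lose-Shift rule with two probabilities: repeat a
    rewarded choice with probability ``p_stay``; leave an unrewarded one
    with probability ``p_shift``.

Sessions are one animal-night each.  Between consecutive nights the Q-values
can be reset to zero, carried over fully, or decayed (partial forgetting);
see :func:`apply_night_carryover`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PROB_FLOOR",
    "ChoiceTrial",
    "Session",
    "AgentState",
    "QLearningParams",
    "PerseverationParams",
    "WSLSParams",
    "ModelSpec",
    "DEFAULT_MODEL_SPECS",
    "softmax_choice_prob",
    "q_update",
    "perseveration_update",
    "choice_prob_perseveration",
    "wsls_choice_prob",
    "apply_night_carryover",
    "negative_log_likelihood",
]

#: Lower bound applied to per-trial probabilities inside the log-likelihood,
#: preventing -inf at extreme parameter values.
PROB_FLOOR = 1e-12

_CARRYOVER_MODES = ("reset", "decay", "full")
_FAMILIES = ("rl", "rl_perseveration", "wsls")

# Box bounds used for fitting and for random starting points.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 20.0),
    "decay": (0.0, 1.0),
    "p_rate": (0.0, 1.0),
    "p_exp": (-10.0, 10.0),
    "p_stay": (0.0, 1.0),
    "p_shift": (0.0, 1.0),
}


@dataclass(frozen=True)
class ChoiceTrial:
    """One decision: which feeder was chosen and whether it paid out."""

    index: int
    action: int
    reward: int
    time_s: float | None = None

    def __post_init__(self) -> None:
        if self.action not in (0, 1):
            raise ValueError(f"action must be 0 or 1, got {self.action!r}")
        if self.reward not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.reward!r}")


@dataclass
class Session:
    """Ordered trials of one animal on one night."""

    bat_id: str
    night: int
    environment: str
    actions: np.ndarray
    rewards: np.ndarray
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.actions = np.asarray(self.actions, dtype=np.int8)
        self.rewards = np.asarray(self.rewards, dtype=np.int8)
        if self.actions.shape != self.rewards.shape or self.actions.ndim != 1:
            raise ValueError("actions and rewards must be 1-D and equal length")
        if not np.isin(self.actions, (0, 1)).all():
            raise ValueError("actions must be 0 or 1")
        if not np.isin(self.rewards, (0, 1)).all():
            raise ValueError("rewards must be 0 or 1")
        if self.times_s is not None:
            self.times_s = np.asarray(self.times_s, dtype=float)
            if self.times_s.shape != self.actions.shape:
                raise ValueError("times_s must match actions in length")

    @property
    def n_trials(self) -> int:
        return int(self.actions.size)

    def to_trials(self) -> list[ChoiceTrial]:
        times = self.times_s if self.times_s is not None else [None] * self.n_trials
        return [
            ChoiceTrial(index=i + 1, action=int(a), reward=int(r),
                        time_s=None if t is None else float(t))
            for i, (a, r, t) in enumerate(zip(self.actions, self.rewards, times))
        ]


@dataclass
class AgentState:
    """Latent state of a learner: action values and perseveration traces."""

    q: np.ndarray = field(default_factory=lambda: np.zeros(2))
    p_val: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).copy()
        self.p_val = np.asarray(self.p_val, dtype=float).copy()
        if self.q.shape != (2,) or self.p_val.shape != (2,):
            raise ValueError("q and p_val must each hold exactly two values")
        if not (np.isfinite(self.q).all() and np.isfinite(self.p_val).all()):
            raise ValueError("state values must be finite")

    def copy(self) -> "AgentState":
        return AgentState(q=self.q.copy(), p_val=self.p_val.copy())


def _check_unit_interval(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class QLearningParams:
    """Parameters of the plain Q-learner (optionally with night decay)."""

    alpha: float
    beta: float
    decay: float | None = None
    carryover_mode: str = "reset"

    def __post_init__(self) -> None:
        _check_unit_interval("alpha", self.alpha)
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.carryover_mode not in _CARRYOVER_MODES:
            raise ValueError(f"unknown carryover mode {self.carryover_mode!r}")
        if self.carryover_mode == "decay":
            if self.decay is None:
                raise ValueError("decay carryover requires a decay value")
            _check_unit_interval("decay", self.decay)
        elif self.decay is not None:
            raise ValueError("decay only applies to the decay carryover mode")

    def as_dict(self) -> dict[str, float]:
        d = {"alpha": self.alpha, "beta": self.beta}
        if self.decay is not None:
            d["decay"] = self.decay
        return d


@dataclass(frozen=True)
class PerseverationParams(QLearningParams):
    """Q-learner parameters plus the perseveration rate and exponent."""

    p_rate: float = 0.0
    p_exp: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_unit_interval("p_rate", self.p_rate)
        if not math.isfinite(self.p_exp):
            raise ValueError("p_exp must be finite")

    def as_dict(self) -> dict[str, float]:
        d = super().as_dict()
        d["p_rate"] = self.p_rate
        d["p_exp"] = self.p_exp
        return d


@dataclass(frozen=True)
class WSLSParams:
    """Win-Stay and Lose-Shift probabilities."""

    p_stay: float
    p_shift: float

    def __post_init__(self) -> None:
        _check_unit_interval("p_stay", self.p_stay)
        _check_unit_interval("p_shift", self.p_shift)

    def as_dict(self) -> dict[str, float]:
        return {"p_stay": self.p_stay, "p_shift": self.p_shift}


@dataclass(frozen=True)
class ModelSpec:
    """Model family + between-night carryover assumption.

    ``decay_convention`` selects how the decay factor ``d`` scales the
    carried-over Q-values: ``"forget"`` (default) applies ``Q <- (1-d)*Q``
    so that higher ``d`` means more forgetting; ``"retain"`` applies
    ``Q <- d*Q`` (the opposite reading).
    """

    family: str = "rl"
    carryover: str = "reset"
    decay_convention: str = "forget"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.carryover not in _CARRYOVER_MODES:
            raise ValueError(f"unknown carryover mode {self.carryover!r}")
        if self.decay_convention not in ("forget", "retain"):
            raise ValueError(f"unknown decay convention {self.decay_convention!r}")

    @property
    def name(self) -> str:
        if self.family == "wsls":
            return "wsls"
        base = "rl" if self.family == "rl" else "rl+persev"
        return f"{base}/{self.carryover}"

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.family == "wsls":
            return ("p_stay", "p_shift")
        names = ["alpha", "beta"]
        if self.carryover == "decay":
            names.append("decay")
        if self.family == "rl_perseveration":
            names += ["p_rate", "p_exp"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(PARAM_BOUNDS[n] for n in self.param_names)

    def make_params(self, values: Mapping[str, float]):
        """Build the typed parameter object for this spec from a mapping."""
        vals = {k: float(values[k]) for k in self.param_names}
        if self.family == "wsls":
            return WSLSParams(**vals)
        common = dict(alpha=vals["alpha"], beta=vals["beta"],
                      decay=vals.get("decay"), carryover_mode=self.carryover)
        if self.family == "rl":
            return QLearningParams(**common)
        return PerseverationParams(**common, p_rate=vals["p_rate"], p_exp=vals["p_exp"])


#: The six Q-learning variants (3 carryover assumptions x with/without
#: perseveration) plus the WSLS model — the full comparison set.
DEFAULT_MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("rl", "reset"),
    ModelSpec("rl", "decay"),
    ModelSpec("rl", "full"),
    ModelSpec("rl_perseveration", "reset"),
    ModelSpec("rl_perseveration", "decay"),
    ModelSpec("rl_perseveration", "full"),
    ModelSpec("wsls"),
)


def softmax_choice_prob(q: Sequence[float] | AgentState, beta: float, action: int) -> float:
    """Probability of choosing ``action`` under the softmax policy.

    P(a) = exp(beta*Q_a) / (exp(beta*Q_a) + exp(beta*Q_b)), computed after
    subtracting the max exponent for numerical stability.
    """
    if isinstance(q, AgentState):
        q = q.q
    q0, q1 = float(q[0]), float(q[1])
    if not (math.isfinite(q0) and math.isfinite(q1) and math.isfinite(beta)):
        raise ValueError("softmax inputs must be finite")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if action not in (0, 1):
        raise ValueError("action must be 0 or 1")
    x0, x1 = beta * q0, beta * q1
    m = x0 if x0 > x1 else x1
    e0, e1 = math.exp(x0 - m), math.exp(x1 - m)
    return (e0 if action == 0 else e1) / (e0 + e1)


def q_update(state: AgentState, chosen: int, reward: int, alpha: float) -> AgentState:
    """Prediction-error update of the chosen action's value.

    Q_chosen <- Q_chosen + alpha * (reward - Q_chosen); the unchosen value
    is not updated.  Returns a new state; the input is left unmodified.
    """
    if chosen not in (0, 1):
        raise ValueError("chosen action must be 0 or 1")
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    _check_unit_interval("alpha", alpha)
    out = state.copy()
    out.q[chosen] += alpha * (reward - out.q[chosen])
    return out


def perseveration_update(state: AgentState, chosen: int, p_rate: float) -> AgentState:
    """Outcome-independent update of the perseveration traces.

    Both traces shrink by (1 - p_rate); the chosen action's trace then gains
    p_rate, pulling it toward 1 while the unchosen trace drifts toward 0.
    """
    if chosen not in (0, 1):
        raise ValueError("chosen action must be 0 or 1")
    _check_unit_interval("p_rate", p_rate)
    out = state.copy()
    out.p_val *= 1.0 - p_rate
    out.p_val[chosen] += p_rate
    return out


def choice_prob_perseveration(state: AgentState, beta: float, p_exp: float, action: int) -> float:
    """Softmax over beta*Q + p_exp*p_val; equals the plain softmax at p_exp=0."""
    if action not in (0, 1):
        raise ValueError("action must be 0 or 1")
    if not (math.isfinite(beta) and math.isfinite(p_exp)):
        raise ValueError("inputs must be finite")
    x0 = beta * state.q[0] + p_exp * state.p_val[0]
    x1 = beta * state.q[1] + p_exp * state.p_val[1]
    m = x0 if x0 > x1 else x1
    e0, e1 = math.exp(x0 - m), math.exp(x1 - m)
    return (e0 if action == 0 else e1) / (e0 + e1)


def wsls_choice_prob(prev: ChoiceTrial, action: int, params: WSLSParams) -> float:
    """Probability of ``action`` given the previous trial, under WSLS.

    Repeating a rewarded choice has probability ``p_stay``; repeating an
    unrewarded one has probability ``1 - p_shift``.  Must not be called for
    the first trial of a night (no previous trial exists).
    """
    if action not in (0, 1):
        raise ValueError("action must be 0 or 1")
    p_same = params.p_stay if prev.reward == 1 else 1.0 - params.p_shift
    return p_same if action == prev.action else 1.0 - p_same


def apply_night_carryover(end_state: AgentState, mode: str,
                          decay: float | None = None,
                          convention: str = "forget") -> AgentState:
    """Transform the Q-values carried from one night into the next.

    ``reset`` zeroes them (learning restarts from scratch), ``full`` keeps
    them (perfect overnight memory), ``decay`` scales them by ``1 - decay``
    (default convention: decay=1 forgets everything, decay=0 keeps all) or
    by ``decay`` under the ``"retain"`` convention.
    """
    if mode not in _CARRYOVER_MODES:
        raise ValueError(f"unknown carryover mode {mode!r}")
    out = end_state.copy()
    if mode == "reset":
        out.q[:] = 0.0
    elif mode == "decay":
        if decay is None:
            raise ValueError("decay carryover requires a decay value")
        _check_unit_interval("decay", decay)
        out.q *= (1.0 - decay) if convention == "forget" else decay
    return out


def _params_as_dict(params) -> dict[str, float]:
    if isinstance(params, Mapping):
        return {k: float(v) for k, v in params.items()}
    return params.as_dict()


def _nll_wsls(sessions: Sequence[Session], p_stay: float, p_shift: float) -> float:
    nll = 0.0
    for s in sessions:
        nll += math.log(2.0)  # first trial of each night: uninformed 0.5
        if s.n_trials > 1:
            prev_a = s.actions[:-1]
            prev_r = s.rewards[:-1]
            cur = s.actions[1:]
            p_same = np.where(prev_r == 1, p_stay, 1.0 - p_shift)
            p_obs = np.where(cur == prev_a, p_same, 1.0 - p_same)
            nll -= float(np.log(np.maximum(p_obs, PROB_FLOOR)).sum())
    return nll


def _nll_rl(sessions: Sequence[Session], spec: ModelSpec, p: Mapping[str, float],
            q_init: tuple[float, float] = (0.0, 0.0)) -> float:
    alpha = p["alpha"]
    beta = p["beta"]
    decay = p.get("decay")
    persev = spec.family == "rl_perseveration"
    p_rate = p.get("p_rate", 0.0)
    p_exp = p.get("p_exp", 0.0)
    exp, log = math.exp, math.log
    floor = PROB_FLOOR

    q0, q1 = float(q_init[0]), float(q_init[1])
    nll = 0.0
    for k, s in enumerate(sessions):
        if k > 0:
            if spec.carryover == "reset":
                q0 = q1 = 0.0
            elif spec.carryover == "decay":
                f = (1.0 - decay) if spec.decay_convention == "forget" else decay
                q0 *= f
                q1 *= f
        pv0 = pv1 = 0.5  # perseveration traces restart each night
        keep = 1.0 - p_rate
        for a, r in zip(s.actions.tolist(), s.rewards.tolist()):
            x0 = beta * q0
            x1 = beta * q1
            if persev:
                x0 += p_exp * pv0
                x1 += p_exp * pv1
            m = x0 if x0 > x1 else x1
            e0 = exp(x0 - m)
            e1 = exp(x1 - m)
            pr = (e0 if a == 0 else e1) / (e0 + e1)
            nll -= log(pr if pr > floor else floor)
            if a == 0:
                q0 += alpha * (r - q0)
            else:
                q1 += alpha * (r - q1)
            if persev:
                pv0 *= keep
                pv1 *= keep
                if a == 0:
                    pv0 += p_rate
                else:
                    pv1 += p_rate
    return nll


def negative_log_likelihood(sessions: Sequence[Session] | Session,
                            spec: ModelSpec,
                            params,
                            q_init: tuple[float, float] = (0.0, 0.0)) -> float:
    """Negative log-likelihood of one animal's sessions under a model.

    Trials accumulate -ln P(observed action).  Latent state propagates
    across trials within a night; between nights the carryover rule of
    ``spec`` is applied to the Q-values while perseveration traces restart
    at (0.5, 0.5).  Q starts at ``q_init`` (default (0, 0)) on the first
    night.  For WSLS the first trial of each night contributes ln 2.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    sessions = list(sessions)
    if not sessions or all(s.n_trials == 0 for s in sessions):
        raise ValueError("need at least one trial to evaluate a likelihood")
    p = _params_as_dict(params)
    if spec.family == "wsls":
        return _nll_wsls(sessions, p["p_stay"], p["p_shift"])
    return _nll_rl(sessions, spec, p, q_init=q_init)
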