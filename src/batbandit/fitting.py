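"""Multi-start maximum-likelihood fitting and information-criterion model
comparison.

Each animal is fitted independently: the negative log-likelihood of its
ordered sessions is minimised with a box-bounded quasi-Newton optimizer
(L-BFGS-B) from many random starting points (50 by default), and the best
start wins.  Models are compared per animal with BIC (and AIC); the
Q-learning and WSLS families both have two free parameters in their base
forms, so their raw log-likelihoods are directly comparable as well.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    DEFAULT_MODEL_SPECS,
    ModelSpec,
    Session,
    negative_log_likelihood,
)

__all__ = [
    "FitResult",
    "FitError",
    "fit_model",
    "information_criteria",
    "compare_models",
    "fit_per_night",
]


class FitError(RuntimeError):
    """Raised when every optimizer start fails; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class FitResult:
    """Outcome of a multi-start ML fit of one model to one animal's data."""

    model: str
    spec: ModelSpec
    params: dict[str, float]
    nll: float
    aic: float
    bic: float
    n_trials: int
    n_starts: int
    start_nlls: np.ndarray
    seed: int | None
    n_converged: int
    metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.spec.n_params

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "nll": self.nll,
            "aic": self.aic,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "n_converged": self.n_converged,
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def information_criteria(nll: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k + 2*NLL and BIC = k*ln(n) + 2*NLL."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if k < 1:
        raise ValueError("k must be at least 1")
    aic = 2.0 * k + 2.0 * nll
    bic = k * math.log(n) + 2.0 * nll
    return aic, bic


def _random_starts(spec: ModelSpec, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform starts within bounds; beta log-uniform in [0.01, 20] for scale.

    Draws are per start, so with a fixed seed the first k starts of a
    larger multi-start run coincide with a k-start run (nested seeds).
    """
    starts = np.empty((n_starts, spec.n_params))
    for i in range(n_starts):
        for j, (name, (lo, hi)) in enumerate(zip(spec.param_names, spec.bounds)):
            if name == "beta":
                starts[i, j] = math.exp(rng.uniform(math.log(0.01), math.log(20.0)))
            else:
                starts[i, j] = rng.uniform(lo, hi)
    return starts


def _minimize_multistart(objective, spec: ModelSpec, n_starts: int,
                         rng: np.random.Generator):
    starts = _random_starts(spec, n_starts, rng)
    best = None
    start_nlls = np.full(n_starts, np.nan)
    n_converged = 0
    diagnostics = []
    for i, x0 in enumerate(starts):
        res = minimize(objective, x0, method="L-BFGS-B", bounds=spec.bounds,
                       options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500})
        start_nlls[i] = res.fun
        if res.success:
            n_converged += 1
            if best is None or res.fun < best.fun:
                best = res
        else:
            diagnostics.append({"start": i, "x0": x0.tolist(),
                                "message": str(res.message), "fun": float(res.fun)})
    if best is None:
        raise FitError(f"all {n_starts} optimizer starts failed for {spec.name}",
                       diagnostics)
    return best, start_nlls, n_converged


def fit_model(sessions: Sequence[Session] | Session, spec: ModelSpec,
              n_starts: int = 50, seed: int | None = None) -> FitResult:
    """Fit one model to one animal's sessions by multi-start bounded MLE.

    Starting points are drawn uniformly within the parameter bounds
    (log-uniformly for beta); the reported fit is the best of the
    ``n_starts`` local optimizations.  Deterministic given ``seed``.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    sessions = list(sessions)
    n_trials = sum(s.n_trials for s in sessions)
    if n_trials < 2:
        raise ValueError("need at least 2 trials to fit a model")
    names = spec.param_names
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        return negative_log_likelihood(sessions, spec, dict(zip(names, x)))

    best, start_nlls, n_converged = _minimize_multistart(objective, spec, n_starts, rng)
    params = {name: float(v) for name, v in zip(names, best.x)}
    aic, bic = information_criteria(best.fun, spec.n_params, n_trials)
    return FitResult(
        model=spec.name, spec=spec, params=params, nll=float(best.fun),
        aic=aic, bic=bic, n_trials=n_trials, n_starts=n_starts,
        start_nlls=start_nlls, seed=seed, n_converged=n_converged,
        metadata={"bounds": {n: b for n, b in zip(names, spec.bounds)}},
    )


def _child_seed(seed: int | None, *labels: str) -> int | None:
    """Stable per-(bat, model) seed: identical labels give identical streams."""
    if seed is None:
        return None
    h = zlib.crc32("|".join(labels).encode())
    return int(np.random.SeedSequence([seed, h]).generate_state(1)[0] % (2**31))


def compare_models(sessions_by_bat: Mapping[str, Sequence[Session]],
                   specs: Sequence[ModelSpec] = DEFAULT_MODEL_SPECS,
                   n_starts: int = 50, seed: int | None = None) -> pd.DataFrame:
    """Fit every model to every animal and tabulate NLL/AIC/BIC.

    Returns one row per (bat, model) with a ``best_bic`` flag marking each
    animal's lowest-BIC model and a ``loglik`` column (-NLL) for the
    equal-parameter-count RL-vs-WSLS comparison.  Fit failures are annotated
    in the ``error`` column rather than aborting the table.
    """
    if not specs:
        raise ValueError("need at least one model spec")
    rows = []
    for bat_id, sessions in sessions_by_bat.items():
        for spec in specs:
            row: dict = {"bat_id": bat_id, "model": spec.name, "k": spec.n_params}
            try:
                fit = fit_model(sessions, spec, n_starts=n_starts,
                                seed=_child_seed(seed, str(bat_id), spec.name))
                row.update(nll=fit.nll, loglik=-fit.nll, aic=fit.aic, bic=fit.bic,
                           n_trials=fit.n_trials, params=json.dumps(fit.params),
                           error=None)
            except Exception as exc:  # annotate per cell, keep going
                row.update(nll=np.nan, loglik=np.nan, aic=np.nan, bic=np.nan,
                           n_trials=np.nan, params=None, error=str(exc))
            rows.append(row)
    table = pd.DataFrame(rows)
    table["best_bic"] = False
    for bat_id, group in table.groupby("bat_id"):
        if group["bic"].notna().any():
            table.loc[group["bic"].idxmin(), "best_bic"] = True
    return table


def _terminal_q(session: Session, alpha: float, q_init: tuple[float, float]) -> tuple[float, float]:
    """Q-values at the end of a night under the plain learner's update rule."""
    q0, q1 = q_init
    for a, r in zip(session.actions.tolist(), session.rewards.tolist()):
        if a == 0:
            q0 += alpha * (r - q0)
        else:
            q1 += alpha * (r - q1)
    return q0, q1


def fit_per_night(sessions: Sequence[Session], spec: ModelSpec | None = None,
                  n_starts: int = 50, seed: int | None = None) -> list[FitResult]:
    """Per-night fits of (alpha, beta, decay) assuming partial overnight memory.

    Night 1 is fitted from Q = (0, 0) with (alpha, beta) free (the decay
    factor plays no role before any memory exists and is reported as NaN).
    For each later night the previous night's fitted parameters generate
    that night's terminal Q trajectory; the current night is then fitted
    with its own free decay scaling the inherited values (forget
    convention: Q_start = (1-d) * Q_previous_end).  A gap in the night
    numbering is treated as consecutive, with a warning.
    """
    if spec is None:
        spec = ModelSpec("rl", "decay")
    if spec.family != "rl" or spec.carryover != "decay":
        raise ValueError("per-night fitting is defined for the rl/decay model")
    sessions = sorted(sessions, key=lambda s: s.night)
    if not sessions:
        raise ValueError("no sessions supplied")
    nights = [s.night for s in sessions]
    if any(b - a > 1 for a, b in zip(nights, nights[1:])):
        warnings.warn("gap in night numbering; treating nights as consecutive",
                      stacklevel=2)

    results: list[FitResult] = []
    q_end = (0.0, 0.0)
    for i, session in enumerate(sessions):
        if i == 0:
            night_spec = ModelSpec("rl", "reset", spec.decay_convention)
            fit = fit_model([session], night_spec, n_starts=n_starts,
                            seed=_child_seed(seed, session.bat_id, f"night{session.night}"))
            fit.params["decay"] = float("nan")
            fit.model = spec.name
            fit.spec = spec
            q_start = (0.0, 0.0)
        else:
            names = spec.param_names  # (alpha, beta, decay)
            q_prev = q_end

            def objective(x: np.ndarray) -> float:
                alpha, beta, d = x
                f = (1.0 - d) if spec.decay_convention == "forget" else d
                return negative_log_likelihood(
                    [session], ModelSpec("rl", "reset", spec.decay_convention),
                    {"alpha": alpha, "beta": beta},
                    q_init=(f * q_prev[0], f * q_prev[1]))

            rng = np.random.default_rng(
                _child_seed(seed, session.bat_id, f"night{session.night}"))
            best, start_nlls, n_conv = _minimize_multistart(objective, spec, n_starts, rng)
            params = {n: float(v) for n, v in zip(names, best.x)}
            aic, bic = information_criteria(best.fun, spec.n_params, session.n_trials)
            fit = FitResult(model=spec.name, spec=spec, params=params,
                            nll=float(best.fun), aic=aic, bic=bic,
                            n_trials=session.n_trials, n_starts=n_starts,
                            start_nlls=start_nlls, seed=seed, n_converged=n_conv)
            d = params["decay"]
            f = (1.0 - d) if spec.decay_convention == "forget" else d
            q_start = (f * q_prev[0], f * q_prev[1])
        fit.metadata.update({
            "night": session.night,
            "q_start": list(q_start),
            "carryover_assumption": ("previous night's trajectory generated by its "
                                     "own fitted parameters, then scaled by this "
                                     "night's fitted decay"),
        })
        q_end = _terminal_q(session, fit.params["alpha"], q_start)
        fit.metadata["q_end"] = list(q_end)
        results.append(fit)
    return results
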