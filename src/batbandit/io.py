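"""Trial-log I/O, configuration handling, and the end-to-end pipeline.

Trial logs are comma-separated UTF-8 text with one row per trial and the
columns ``bat_id, environment, night, trial_index, time_s, feeder, reward``.
Metadata and reports are JSON.  :func:`run_pipeline` chains the full
analysis: model comparison across the seven candidate models, per-night
fits of the decaying Q-learner, descriptive behaviour statistics with QC,
optimal-learning-rate grid searches, the WSLS success-rate grid, and the
empirical percentile comparison of observed versus simulated success.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import _child_seed, compare_models, fit_model, fit_per_night
from .metrics import qc_filter, reward_effect, success_rate
from .models import DEFAULT_MODEL_SPECS, ModelSpec, Session
from .simulation import grid_search_alpha, percentile_test, wsls_grid
from .synth import CohortConfig, generate_cohort

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "TrialLogError",
    "read_trial_log",
    "write_trial_log",
    "sessions_from_frame",
    "sessions_to_frame",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger("batbandit")

TRIAL_LOG_COLUMNS = ("bat_id", "environment", "night", "trial_index",
                     "time_s", "feeder", "reward")


class TrialLogError(ValueError):
    """Schema violation in a trial log; lists the offending rows."""


def _validate_frame(frame: pd.DataFrame, source: str = "<frame>") -> pd.DataFrame:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"{source}: missing columns {missing}")
    problems = []
    for col, ok in [
        ("environment", frame["environment"].isin(["stable", "volatile"])),
        ("night", pd.to_numeric(frame["night"], errors="coerce").isin(range(1, 100))),
        ("trial_index", pd.to_numeric(frame["trial_index"], errors="coerce") >= 1),
        ("feeder", pd.to_numeric(frame["feeder"], errors="coerce").isin([0, 1])),
        ("reward", pd.to_numeric(frame["reward"], errors="coerce").isin([0, 1])),
    ]:
        bad = frame.index[~ok]
        # +2: header line plus 1-based numbering, matching the file layout
        problems += [f"column {col!r} invalid at row {i + 2} "
                     f"(value {frame.at[i, col]!r})" for i in bad[:10]]
    if problems:
        raise TrialLogError(f"{source}: " + "; ".join(problems))
    frame = frame.copy()
    for col in ("night", "trial_index", "feeder", "reward"):
        frame[col] = frame[col].astype(int)
    frame["time_s"] = frame["time_s"].astype(float)
    sort_cols = ["bat_id", "night", "trial_index"]
    if not frame[sort_cols].equals(frame[sort_cols].sort_values(sort_cols)):
        warnings.warn(f"{source}: rows not sorted by (bat_id, night, trial_index); "
                      "sorting on read", stacklevel=3)
        frame = frame.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    return frame


def sessions_from_frame(frame: pd.DataFrame) -> list[Session]:
    """Split a validated trial-log frame into per-(bat, night) sessions."""
    frame = _validate_frame(frame)
    sessions = []
    for (bat_id, night), g in frame.groupby(["bat_id", "night"], sort=True):
        g = g.sort_values("trial_index")
        sessions.append(Session(
            bat_id=str(bat_id), night=int(night),
            environment=str(g["environment"].iloc[0]),
            actions=g["feeder"].to_numpy(), rewards=g["reward"].to_numpy(),
            times_s=g["time_s"].to_numpy()))
    return sessions


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        times = s.times_s if s.times_s is not None else np.full(s.n_trials, np.nan)
        for i in range(s.n_trials):
            rows.append((s.bat_id, s.environment, s.night, i + 1,
                         float(times[i]), int(s.actions[i]), int(s.rewards[i])))
    return pd.DataFrame(rows, columns=list(TRIAL_LOG_COLUMNS))


def read_trial_log(path: str | Path) -> list[Session]:
    """Read and validate a delimited trial log into ordered sessions."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    return sessions_from_frame(_validate_frame(frame, source=str(path)))


def write_trial_log(data: pd.DataFrame | Sequence[Session], path: str | Path) -> None:
    frame = data if isinstance(data, pd.DataFrame) else sessions_to_frame(data)
    frame.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) pipeline configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 0,
    "input": None,            # path to a trial log; None -> synthetic cohort
    "synthetic": {},          # CohortConfig overrides
    "fitting": {"n_starts": 50},
    "simulation": {"n_agents": 108, "n_trials": 2000, "n_sims": 100},
    "qc": True,
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _behavior_table(sessions: Sequence[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        try:
            summary = reward_effect(s)
        except ValueError:
            continue
        rows.append({"bat_id": s.bat_id, "environment": s.environment,
                     "night": s.night, "n_trials": s.n_trials,
                     "success_rate": summary.success_rate,
                     "p_stay_given_reward": summary.p_stay_given_reward,
                     "p_stay_given_no_reward": summary.p_stay_given_no_reward,
                     "reward_effect": summary.reward_effect})
    return pd.DataFrame(rows)


def run_pipeline(config: Mapping | str | Path | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full analysis and return (and optionally write) a report bundle.

    Stages: load or synthesise data -> fit the seven candidate models per
    bat and tabulate BIC -> per-night decaying-Q-learner fits -> behaviour
    summaries with QC -> learning-rate grid search per environment -> WSLS
    parameter grid -> percentile tests of observed vs simulated success.
    Every random stage derives its stream from the single master seed; a
    failed stage marks the bundle partial instead of aborting it.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    cfg = _merge(DEFAULT_PIPELINE_CONFIG, config or {})
    seed = cfg["seed"]
    bundle: dict = {"config": cfg, "seed": seed, "config_hash": _config_hash(cfg),
                    "stages": {}, "partial": False, "notes": []}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                bundle["stages"][name] = {"status": "ok"}
            except Exception as exc:
                logger.exception("stage %s failed", name)
                bundle["stages"][name] = {"status": "error", "error": str(exc)}
                bundle["partial"] = True
            bundle["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)
            logger.info("stage %s: %s", name, bundle["stages"][name])
        return wrap

    state: dict = {}

    @stage("data")
    def _load():
        if cfg["input"]:
            sessions = read_trial_log(cfg["input"])
            bundle["data_source"] = str(cfg["input"])
        else:
            synth_cfg = CohortConfig(**cfg["synthetic"])
            frame, truth = generate_cohort(synth_cfg, seed=seed)
            sessions = sessions_from_frame(frame)
            bundle["data_source"] = "synthetic"
            bundle["ground_truth"] = json.loads(truth.to_json())
        by_bat: dict[str, list[Session]] = {}
        for s in sessions:
            by_bat.setdefault(s.bat_id, []).append(s)
        state["sessions"] = sessions
        state["by_bat"] = by_bat
        state["envs"] = sorted({s.environment for s in sessions})

    @stage("model_comparison")
    def _compare():
        table = compare_models(state["by_bat"], DEFAULT_MODEL_SPECS,
                               n_starts=cfg["fitting"]["n_starts"], seed=seed)
        bundle["model_comparison"] = table
        best = table.loc[table["best_bic"], ["bat_id", "model"]]
        bundle["bic_winner_counts"] = best["model"].value_counts().to_dict()

    @stage("per_night_fits")
    def _per_night():
        rows = []
        for bat_id, sessions in state["by_bat"].items():
            for fit in fit_per_night(sessions, n_starts=cfg["fitting"]["n_starts"],
                                     seed=seed):
                rows.append({"bat_id": bat_id, "night": fit.metadata["night"],
                             "environment": sessions[0].environment,
                             **fit.params, "nll": fit.nll})
        bundle["per_night_params"] = pd.DataFrame(rows)

    @stage("behavior")
    def _behavior():
        table = _behavior_table(state["sessions"])
        if cfg["qc"] and not table.empty:
            table, exclusions = qc_filter(table)
            bundle["qc_exclusions"] = exclusions
        bundle["behavior"] = table

    @stage("grid_search")
    def _grid():
        sim = cfg["simulation"]
        curves = {}
        for env in state["envs"]:
            curves[env] = grid_search_alpha(
                env, n_agents=sim["n_agents"], n_trials=sim["n_trials"],
                seed=_child_seed(seed, "grid", env))
        bundle["grid_search"] = curves
        for env in ("stable", "volatile"):
            if env not in curves:
                bundle["notes"].append(f"{env}-specific outputs absent: no "
                                       f"{env} sessions in the input")

    @stage("wsls_grid")
    def _wsls():
        sim = cfg["simulation"]
        bundle["wsls_grid"] = {
            env: wsls_grid(env, n_sims=sim["n_sims"], n_trials=sim["n_trials"],
                           seed=_child_seed(seed, "wsls", env))
            for env in state["envs"]}

    @stage("percentile_tests")
    def _percentile():
        verdicts = {}
        behavior = bundle.get("behavior")
        for env in state["envs"]:
            sub = behavior[behavior["environment"] == env] if behavior is not None else None
            if sub is None or sub.empty:
                continue
            observed = float(sub.groupby("bat_id")["success_rate"].mean().mean())
            entry = {"observed_success": observed}
            grid_res = bundle.get("grid_search", {}).get(env)
            if grid_res is not None:
                best_idx = int(np.argmax(grid_res.mean_success))
                sims = grid_res.per_agent_success[best_idx]
                res = percentile_test(observed, sims)
                entry["vs_rl_optimal"] = {"best_alpha": grid_res.best_alpha,
                                          "tail": res.tail, "rank_low": res.rank_low,
                                          "rank_high": res.rank_high,
                                          "n": res.n_simulations}
            wsls_res = bundle.get("wsls_grid", {}).get(env)
            comp = bundle.get("model_comparison")
            if wsls_res is not None and comp is not None:
                fits = comp[(comp["model"] == "wsls") & comp["params"].notna()]
                fits = fits[fits["bat_id"].isin(sub["bat_id"].unique())]
                if not fits.empty:
                    ps = np.mean([json.loads(p)["p_stay"] for p in fits["params"]])
                    pf = np.mean([json.loads(p)["p_shift"] for p in fits["params"]])
                    i = int(np.argmin(np.abs(wsls_res.p_stay_grid - ps)))
                    j = int(np.argmin(np.abs(wsls_res.p_shift_grid - pf)))
                    sims = wsls_res.per_sim_success[i, j]
                    res = percentile_test(observed, sims)
                    entry["vs_wsls_fitted"] = {
                        "p_stay": float(ps), "p_shift": float(pf),
                        "grid_cell": [float(wsls_res.p_stay_grid[i]),
                                      float(wsls_res.p_shift_grid[j])],
                        "simulated_mean": float(sims.mean()),
                        "tail": res.tail, "rank_low": res.rank_low,
                        "rank_high": res.rank_high, "n": res.n_simulations}
            verdicts[env] = entry
        bundle["percentile_tests"] = verdicts

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = []

    def save_frame(name: str, frame: pd.DataFrame):
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        artifacts.append(path.name)

    for key in ("model_comparison", "per_night_params", "behavior", "qc_exclusions"):
        if isinstance(bundle.get(key), pd.DataFrame):
            save_frame(key, bundle[key])
    for env, res in bundle.get("grid_search", {}).items():
        save_frame(f"grid_search_{env}", pd.DataFrame({
            "alpha": res.grid, "mean_success": res.mean_success,
            "sd_success": res.sd_success}))
    for env, res in bundle.get("wsls_grid", {}).items():
        save_frame(f"wsls_grid_{env}", pd.DataFrame(
            res.mean_success, index=pd.Index(res.p_stay_grid, name="p_stay"),
            columns=res.p_shift_grid).reset_index())
    manifest = {
        "seed": bundle["seed"], "config": bundle["config"],
        "config_hash": bundle["config_hash"], "stages": bundle["stages"],
        "partial": bundle["partial"], "notes": bundle["notes"],
        "data_source": bundle.get("data_source"),
        "bic_winner_counts": bundle.get("bic_winner_counts"),
        "percentile_tests": bundle.get("percentile_tests"),
        "artifacts": artifacts,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
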