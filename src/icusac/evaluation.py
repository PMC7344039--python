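"""Accuracy-rate, dose-MSE, convergence-speed and run-comparison reporting.

The two headline metrics mirror how offline treatment policies are scored
against clinician behaviour:

* **AR (accuracy rate)** — fraction of test states where the learned greedy
  action equals the clinician's logged action;
* **dose MSE** — mean squared difference between the predicted and logged
  sedative dose after mapping bins through a dose grid.

Both are reported overall and per stratum (expert / single intubation /
multiple intubation). Convergence speed is summarised as the first episode
at which a learning-curve metric crosses a threshold and stays there for a
patience window.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mdp import Stratum, Trajectory, stratify
from .training import TrainResult, build_stage_arrays

__all__ = [
    "accuracy_rate",
    "dose_mse",
    "episodes_to_threshold",
    "evaluate_policy",
    "compare_runs",
    "plot_learning_curves",
]


def _stage_arrays(result: TrainResult, test_set: Sequence[Trajectory],
                  vent_policy: TrainResult | None):
    """Test arrays for the result's stage; for the sedation stage the 14th
    feature (ventilation action) can come from a learned ventilation policy
    instead of the clinician's log."""
    arrays = build_stage_arrays(test_set, result.cfg.stage)
    if len(arrays) == 0:
        raise ValueError("empty test set")
    if vent_policy is not None:
        if result.cfg.stage != "sed":
            raise ValueError("vent_policy only applies to sedation-stage evaluation")
        vent_states = build_stage_arrays(test_set, "vent").states
        arrays.states[:, 13] = vent_policy.greedy(vent_states)
    return arrays


def accuracy_rate(
    result: TrainResult,
    test_set: Sequence[Trajectory],
    vent_policy: TrainResult | None = None,
) -> float:
    """Fraction of test states where the greedy action matches the clinician label."""
    arrays = _stage_arrays(result, test_set, vent_policy)
    pred = result.greedy(arrays.states)
    return float(np.mean(pred == arrays.actions))


def dose_mse(
    result: TrainResult,
    test_set: Sequence[Trajectory],
    dose_map: Sequence[float] | None = None,
    vent_policy: TrainResult | None = None,
) -> float:
    """Mean squared predicted-vs-logged sedative dose on a sedation-stage test set.

    Dose bins are mapped to doses through ``dose_map`` (defaults to the
    config's grid, bins 0..3 -> doses 0..3).
    """
    if result.cfg.stage != "sed":
        raise ValueError("dose_mse requires a sedation-stage policy")
    arrays = _stage_arrays(result, test_set, vent_policy)
    dm = np.asarray(dose_map if dose_map is not None else result.cfg.dose_map)
    pred = result.greedy(arrays.states)
    return float(np.mean((dm[pred] - dm[arrays.actions]) ** 2))


def episodes_to_threshold(
    curve: pd.DataFrame,
    metric: str = "ar",
    threshold: float = 0.95,
    patience: int = 3,
    direction: str = "above",
) -> int | None:
    """First episode where the metric crosses the threshold and stays there.

    A crossing counts when the metric is at or beyond the threshold for
    ``patience`` consecutive episodes (a window truncated by the end of the
    curve counts if every remaining episode qualifies). Returns the episode
    index, or None when the threshold is never sustainably reached.
    """
    if len(curve) == 0:
        raise ValueError("empty learning curve")
    vals = curve[metric].to_numpy()
    ok = vals >= threshold if direction == "above" else vals <= threshold
    for i in range(len(ok)):
        window = ok[i : i + patience]
        if window.all():
            return int(curve["episode"].iloc[i])
    return None


def evaluate_policy(
    result: TrainResult,
    test_set: Sequence[Trajectory],
    dose_map: Sequence[float] | None = None,
) -> dict:
    """Overall and per-stratum report for one trained policy.

    Returns a dict with ``ar`` (and ``mse`` for sedation policies) overall
    and under ``strata`` per stratum; strata are assigned on the fly when
    the trajectories do not carry them yet.
    """
    if any(t.stratum is None for t in test_set):
        stratify(test_set)
    report: dict = {"stage": result.cfg.stage, "algorithm": result.cfg.algorithm,
                    "n_admissions": len(test_set), "ar": accuracy_rate(result, test_set)}
    if result.cfg.stage == "sed":
        report["mse"] = dose_mse(result, test_set, dose_map)
    strata: dict = {}
    for stratum in Stratum:
        subset = [t for t in test_set if t.stratum is stratum]
        if not subset:
            strata[stratum.value] = {"n_admissions": 0}
            continue
        entry = {"n_admissions": len(subset), "ar": accuracy_rate(result, subset)}
        if result.cfg.stage == "sed":
            entry["mse"] = dose_mse(result, subset, dose_map)
        strata[stratum.value] = entry
    report["strata"] = strata
    return report


def compare_runs(
    runs: Mapping[str, tuple[TrainResult, Sequence[Trajectory]]],
    ar_threshold: float = 0.95,
    patience: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side comparison of named runs on their test sets.

    ``runs`` maps a run name to (trained policy, test trajectories). All
    runs must share the MDP stage. Returns (per-stratum table, aligned
    per-episode curves); the table has one row per run and stratum plus an
    'overall' row per run.
    """
    stages = {res.cfg.stage for res, _ in runs.values()}
    if len(stages) > 1:
        raise ValueError(f"runs mix MDP stages: {sorted(stages)}")
    rows = []
    curves = []
    for name, (result, test_set) in runs.items():
        report = evaluate_policy(result, test_set)
        ep = episodes_to_threshold(result.curve, "ar", ar_threshold, patience)
        base = {"run": name, "algorithm": result.cfg.algorithm,
                "episodes_to_ar_threshold": ep if ep is not None else np.nan}
        rows.append({**base, "stratum": "overall", "ar": report["ar"],
                     "mse": report.get("mse", np.nan),
                     "n_admissions": report["n_admissions"]})
        for stratum, entry in report["strata"].items():
            rows.append({**base, "stratum": stratum, "ar": entry.get("ar", np.nan),
                         "mse": entry.get("mse", np.nan),
                         "n_admissions": entry["n_admissions"]})
        c = result.curve.copy()
        c.insert(0, "run", name)
        curves.append(c)
    return pd.DataFrame(rows), pd.concat(curves, ignore_index=True)


def seed_median(values: Sequence[float | None]) -> float:
    """Median over seeds; a run that never reached the threshold counts as +inf."""
    arr = np.array([np.inf if v is None else float(v) for v in values])
    return float(np.median(arr))


def plot_learning_curves(
    curves: pd.DataFrame, metric: str, out_path: str | Path, ylabel: str | None = None
) -> None:
    """Per-episode metric curves of several runs on one axis (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for run, grp in curves.groupby("run"):
        ax.plot(grp["episode"], grp[metric], label=str(run))
    ax.set_xlabel("episode")
    ax.set_ylabel(ylabel or metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
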