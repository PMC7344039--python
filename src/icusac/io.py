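"""Plain-text file formats: trajectory CSV, strata sidecar, raw-measurement CSVs.

The trajectory dialect is one row per 10-minute step::

    admission_id,t_index,resp_rate,heart_rate,art_ph,peep,spo2,fio2,pao2,
    plateau_p,mean_airway_p,mean_nibp,weight,age,vent_status,vent_action,
    sed_bin,reward_total

Floats are written with Python's shortest round-trip ``repr``, so a
read -> write cycle reproduces the file byte for byte.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from .mdp import (
    STATE_FEATURES,
    CompositeAction,
    PatientState,
    RewardBreakdown,
    Stratum,
    Trajectory,
    Transition,
)

TRAJECTORY_COLUMNS = (
    ["admission_id", "t_index"]
    + list(STATE_FEATURES)
    + ["vent_action", "sed_bin", "reward_total"]
)


def _fmt(x: float) -> str:
    # shortest exact decimal representation; integers stay integer-looking
    return repr(float(x)) if not float(x).is_integer() else str(int(x))


def write_trajectories_csv(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Write trajectories in the trajectory CSV dialect (with rewards)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRAJECTORY_COLUMNS)
        for traj in trajectories:
            for t, tr in enumerate(traj.transitions):
                vec = tr.state.to_vector()
                row = [traj.admission_id, t]
                row += [_fmt(v) for v in vec[:12]]
                row += [int(vec[12]), tr.clinician_action.vent, tr.clinician_action.sedative_bin]
                row += [_fmt(tr.reward.total)]
                writer.writerow(row)
            # closing row: the final next-state with no action (end of stay)
            vec = traj.transitions[-1].next_state.to_vector()
            row = [traj.admission_id, len(traj.transitions)]
            row += [_fmt(v) for v in vec[:12]]
            row += [int(vec[12]), "", "", ""]
            writer.writerow(row)


def read_trajectories_csv(path: str | Path) -> list[Trajectory]:
    """Read the trajectory CSV dialect back into :class:`Trajectory` objects.

    The reward column is optional; missing rewards are stored as zero-total
    breakdowns. The last row of each admission is the closing state.
    """
    path = Path(path)
    rows_by_adm: dict[str, list[dict]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in TRAJECTORY_COLUMNS[:-1] if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {missing}")
        for rec in reader:
            adm = rec["admission_id"]
            if adm not in rows_by_adm:
                rows_by_adm[adm] = []
                order.append(adm)
            rows_by_adm[adm].append(rec)

    trajectories = []
    for adm in order:
        rows = sorted(rows_by_adm[adm], key=lambda r: int(r["t_index"]))
        states = [
            PatientState(
                **{n: float(r[n]) for n in STATE_FEATURES[:12]},
                vent_status=int(float(r["vent_status"])),
            )
            for r in rows
        ]
        transitions = []
        for t in range(len(rows) - 1):
            r = rows[t]
            action = CompositeAction(vent=int(r["vent_action"]), sedative_bin=int(r["sed_bin"]))
            raw_reward = r.get("reward_total", "")
            reward = (
                RewardBreakdown.from_total(float(raw_reward))
                if raw_reward not in ("", None)
                else RewardBreakdown.from_total(0.0)
            )
            transitions.append(
                Transition(
                    state=states[t],
                    action=action,
                    reward=reward,
                    next_state=states[t + 1],
                    terminal=(t == len(rows) - 2),
                    clinician_action=action,
                )
            )
        if not transitions:
            raise ValueError(f"admission {adm!r} has fewer than 2 rows")
        trajectories.append(Trajectory(admission_id=adm, transitions=transitions))
    return trajectories


def write_strata_csv(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Write the `admission_id,stratum` sidecar."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["admission_id", "stratum"])
        for traj in trajectories:
            writer.writerow([traj.admission_id, traj.stratum.value if traj.stratum else ""])


def read_strata_csv(path: str | Path) -> dict[str, Stratum]:
    df = pd.read_csv(path, dtype=str)
    return {row.admission_id: Stratum(row.stratum) for row in df.itertuples()}


def apply_strata(trajectories: Sequence[Trajectory], strata: dict[str, Stratum]) -> None:
    for traj in trajectories:
        if traj.admission_id in strata:
            traj.stratum = strata[traj.admission_id]
            traj.expert = traj.stratum is Stratum.EXPERT
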