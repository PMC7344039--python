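"""Synthetic ICU cohort generator.

Real cohorts for this problem come from credentialed ICU databases and cannot
be bundled. This module generates labeled admissions with the statistical
structure the learners assume:

* each admission carries a scalar latent health ``h_t`` following a
  mean-reverting recovery process (sick on admission, drifting toward
  recovery, perturbed by noise);
* the 12 observable vitals are affine read-outs of ``h_t`` plus independent
  per-feature noise, calibrated so that vitals sit inside their normal
  ranges when the patient is healthy and outside them when not;
* a deterministic clinician policy thresholds a health score reconstructed
  from the vitals to decide weaning, and maps the score through ordered
  breakpoints to a sedative bin; with probability ``clinician_noise`` the
  logged action is replaced by a uniformly random one;
* weaning while the health score is still below the weaning threshold
  triggers reintubation with configurable probability after a short delay,
  which produces the multiple-intubation stratum.

Sedation is not inert: higher dose bins damp the health-process noise but
add a small recovery drag, so the sedation decision problem has a real
reward trade-off.

Everything is driven by one ``numpy`` generator seeded from the config, so a
cohort is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mdp import (
    NORMAL_RANGES,
    VITAL_FEATURES,
    CompositeAction,
    PatientState,
    RewardConfig,
    Trajectory,
    Transition,
    compute_reward,
    stratify,
)

__all__ = [
    "ClinicianPolicy",
    "SimulatorConfig",
    "health_score",
    "clinician_policy",
    "simulate_cohort",
]

#: deviation direction of each ranged vital when the patient deteriorates
#: (+1: value rises above its range when sick; -1: value falls below it)
_DIRECTIONS: dict[str, float] = {
    "resp_rate": +1.0,
    "heart_rate": +1.0,
    "art_ph": -1.0,
    "peep": +1.0,
    "spo2": -1.0,
    "fio2": +1.0,
    "pao2": -1.0,
    "plateau_p": +1.0,
    "mean_airway_p": +1.0,
    "mean_nibp": -1.0,
}

#: how many half-widths a vital deviates from its range midpoint at h = 0
_SICK_DEVIATION = 1.5


@dataclass(frozen=True)
class ClinicianPolicy:
    """Deterministic clinician decision rule on the reconstructed health score.

    Weaning is ordered once the score reaches ``wean_threshold``. The rule
    has hysteresis: an extubated patient (vent status 0) is reintubated only
    if the score falls more than ``reintubation_margin`` below the weaning
    threshold, so the decision does not flap on score noise just below the
    threshold. Both branches are deterministic functions of the
    13-dimensional state (which includes the ventilation status).

    The sedative bin decreases as health improves: a score below the first
    breakpoint gets the deepest sedation (bin 3), a score at or above the
    last breakpoint gets the lightest (bin 0). A score exactly at a
    breakpoint belongs to the upper (healthier) interval.
    """

    wean_threshold: float = 0.6
    reintubation_margin: float = 0.15
    sed_breakpoints: tuple[float, float, float] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        bp = self.sed_breakpoints
        if not (bp[0] < bp[1] < bp[2]):
            raise ValueError("sed_breakpoints must be strictly increasing")


@dataclass(frozen=True)
class SimulatorConfig:
    """Cohort-level generator settings (the study conditions).

    Defaults give a 200-admission cohort with a mean stay of 72 ten-minute
    steps (12 h), 5% clinician label noise, a 30% expert (noise-free)
    subset, and a 70% chance that a premature wean ends in reintubation.
    """

    n_admissions: int = 200
    seed: int = 0
    mean_stay: int = 72
    latent_recovery_rate: float = 0.04
    vital_noise_sd: float = 0.08
    clinician_noise: float = 0.05
    reintubation_prob_if_early: float = 0.7
    expert_fraction: float = 0.3
    health_noise_sd: float = 0.02
    sed_recovery_drag: float = 0.004
    sed_noise_relief: float = 0.15
    reward_cfg: RewardConfig = field(default_factory=RewardConfig)
    policy: ClinicianPolicy = field(default_factory=ClinicianPolicy)

    def __post_init__(self) -> None:
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")
        for name in ("clinician_noise", "reintubation_prob_if_early", "expert_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


def _range_mid_half(name: str) -> tuple[float, float]:
    lo, hi = NORMAL_RANGES[name]
    return (lo + hi) / 2.0, (hi - lo) / 2.0


def _vitals_from_health(h: float, demo: dict[str, float], noise: np.ndarray) -> dict[str, float]:
    """Affine read-out of the latent health into the 12 vitals."""
    vals: dict[str, float] = {}
    for i, name in enumerate(_DIRECTIONS):
        mid, half = _range_mid_half(name)
        vals[name] = mid + (_DIRECTIONS[name] * _SICK_DEVIATION * (1.0 - h) + noise[i]) * half
    vals["weight"] = demo["weight"]
    vals["age"] = demo["age"]
    return vals


def health_score(state: PatientState) -> float:
    """Reconstruct the latent health from the observable vitals.

    Inverts the affine read-out and averages over the ranged vitals; the
    result equals the latent health up to the (small) read-out noise and is
    a deterministic function of the state — which is what makes the
    clinician labels learnable from the state alone.
    """
    dev = 0.0
    for name, direction in _DIRECTIONS.items():
        mid, half = _range_mid_half(name)
        dev += (getattr(state, name) - mid) / (direction * _SICK_DEVIATION * half)
    return 1.0 - dev / len(_DIRECTIONS)


def clinician_policy(state: PatientState, pol: ClinicianPolicy) -> CompositeAction:
    """Deterministic clinician action for a state (wean decision + sedative bin)."""
    score = health_score(state)
    if state.vent_status == 1:
        vent = 1 if score >= pol.wean_threshold else 0
    else:
        vent = 0 if score < pol.wean_threshold - pol.reintubation_margin else 1
    interval = int(np.searchsorted(np.asarray(pol.sed_breakpoints), score, side="right"))
    return CompositeAction(vent=vent, sedative_bin=3 - interval)


def _simulate_admission(
    adm_id: str,
    cfg: SimulatorConfig,
    rng: np.random.Generator,
    expert: bool,
) -> Trajectory:
    n_steps = max(24, int(round(rng.normal(cfg.mean_stay, cfg.mean_stay / 4))))
    demo = {
        "weight": float(rng.normal(78.0, 12.0)),
        "age": float(rng.uniform(30.0, 90.0)),
    }
    h = float(rng.uniform(0.15, 0.45))
    vent_status = 1  # intubated on admission
    noise_mat = rng.normal(0.0, cfg.vital_noise_sd, size=(n_steps + 1, len(_DIRECTIONS)))

    states: list[PatientState] = []
    actions: list[CompositeAction] = []
    scores: list[float] = []
    reintubation_due: int | None = None

    for t in range(n_steps + 1):
        state = PatientState(
            **_vitals_from_health(h, demo, noise_mat[t]), vent_status=vent_status
        )
        states.append(state)
        if t == n_steps:
            break

        score = health_score(state)
        scores.append(score)
        action = clinician_policy(state, cfg.policy)
        if not expert and rng.random() < cfg.clinician_noise:
            # label deviation: the sedative bin is re-drawn uniformly, and the
            # wean decision is re-drawn only while the patient is ventilated —
            # charted deviations do not spuriously reintubate a stable,
            # already-extubated patient
            vent = int(rng.integers(0, 2)) if vent_status == 1 else action.vent
            action = CompositeAction(vent=vent, sedative_bin=int(rng.integers(0, 4)))
        actions.append(action)

        # ventilation dynamics: the action sets the desired status; a
        # premature wean may schedule a forced reintubation shortly after
        next_status = 0 if action.vent == 1 else 1
        if action.vent == 1 and vent_status == 1 and score < cfg.policy.wean_threshold:
            if rng.random() < cfg.reintubation_prob_if_early:
                reintubation_due = t + 1 + int(rng.integers(0, 6))
        if reintubation_due is not None and t + 1 >= reintubation_due:
            next_status = 1
            reintubation_due = None
        vent_status = next_status

        # latent health dynamics: mean-reverting recovery, sedation damps
        # noise but drags recovery
        sed = action.sedative_bin
        drift = cfg.latent_recovery_rate * (1.0 - h) - cfg.sed_recovery_drag * sed
        shock = cfg.health_noise_sd * (1.0 - cfg.sed_noise_relief * sed / 3.0) * rng.normal()
        h = float(np.clip(h + drift + shock, 0.0, 1.05))

    # rewards need look-ahead: was a wean followed by reintubation in-window?
    status_seq = [s.vent_status for s in states]
    flips = [
        u
        for u in range(1, len(status_seq))
        if status_seq[u - 1] == 0 and status_seq[u] == 1
    ]
    transitions = []
    for t in range(n_steps):
        reintub = False
        if actions[t].vent == 1 and states[t].vent_status == 1:
            horizon = min(t + cfg.reward_cfg.window_steps, n_steps)
            reintub = any(t < u <= horizon for u in flips) or status_seq[t + 1] == 1
        reward = compute_reward(
            states[t], actions[t], states[t + 1], cfg.reward_cfg,
            reintubation_follows=reintub,
        )
        transitions.append(
            Transition(
                state=states[t],
                action=actions[t],
                reward=reward,
                next_state=states[t + 1],
                terminal=(t == n_steps - 1),
                clinician_action=actions[t],
            )
        )
    return Trajectory(admission_id=adm_id, transitions=transitions, expert=expert)


def simulate_cohort(cfg: SimulatorConfig) -> list[Trajectory]:
    """Generate a labeled cohort of admissions; bit-reproducible given the seed.

    Each trajectory is assigned its reporting stratum: expert (noise-free
    labels) takes precedence, the rest split by intubation count.
    """
    rng = np.random.default_rng(cfg.seed)
    trajectories = []
    for i in range(cfg.n_admissions):
        expert = cfg.clinician_noise == 0.0 or rng.random() < cfg.expert_fraction
        trajectories.append(_simulate_admission(f"adm{i:05d}", cfg, rng, expert))
    stratify(trajectories)
    return trajectories
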