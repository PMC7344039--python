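"""Markov decision processes for ventilation weaning and sedative dosing.

Two coupled decision problems are modelled on a 10-minute time grid:

* **Ventilation MDP** — the state is a 13-dimensional vector (12 physiological /
  ventilator features plus the current ventilation status) and the binary action
  is whether to wean the patient off the ventilator.
* **Sedation MDP** — the state is the 13-dimensional vector augmented with the
  ventilation action just taken (14 dimensions), and the action is a propofol
  dose discretised into 4 bins.

The joint action space therefore has 2 x 4 = 8 composite actions, one-hot
encoded per component (a length-2 and a length-4 block).

The per-step reward decomposes into three additive parts::

    r = r_vitals + r_vent_off + r_vent_on

``r_vitals`` scores physiological stability (fraction of configured vitals
inside their normal range after the transition), ``r_vent_off`` rewards a
weaning decision that is not followed by reintubation within a configurable
window and penalises one that is, and ``r_vent_on`` charges a cost for every
step spent on the ventilator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VITAL_FEATURES",
    "STATE_FEATURES",
    "NORMAL_RANGES",
    "PatientState",
    "SedationState",
    "CompositeAction",
    "RewardBreakdown",
    "RewardConfig",
    "Transition",
    "Trajectory",
    "Stratum",
    "compute_reward",
    "discounted_return",
    "encode_action",
    "decode_action",
    "build_sedation_state",
]

#: the 12 physiological / ventilator features, in state-vector order
VITAL_FEATURES: tuple[str, ...] = (
    "resp_rate",
    "heart_rate",
    "art_ph",
    "peep",
    "spo2",
    "fio2",
    "pao2",
    "plateau_p",
    "mean_airway_p",
    "mean_nibp",
    "weight",
    "age",
)

#: full 13-dimensional state: vitals followed by the ventilation status bit
STATE_FEATURES: tuple[str, ...] = VITAL_FEATURES + ("vent_status",)

#: default normal ranges for the vitals that enter the stability reward.
#: weight and age are demographic context, not stability targets, and carry
#: no range by default.
NORMAL_RANGES: dict[str, tuple[float, float]] = {
    "resp_rate": (12.0, 24.0),      # breaths/min
    "heart_rate": (60.0, 100.0),    # beats/min
    "art_ph": (7.35, 7.45),         # pH units
    "peep": (4.0, 10.0),            # cmH2O
    "spo2": (94.0, 100.0),          # %
    "fio2": (0.21, 0.5),            # fraction
    "pao2": (75.0, 110.0),          # mmHg
    "plateau_p": (10.0, 30.0),      # cmH2O
    "mean_airway_p": (8.0, 16.0),   # cmH2O
    "mean_nibp": (70.0, 105.0),     # mmHg
}


@dataclass(frozen=True)
class PatientState:
    """13-dimensional patient state for the ventilation MDP."""

    resp_rate: float
    heart_rate: float
    art_ph: float
    peep: float
    spo2: float
    fio2: float
    pao2: float
    plateau_p: float
    mean_airway_p: float
    mean_nibp: float
    weight: float
    age: float
    vent_status: int

    def __post_init__(self) -> None:
        if self.vent_status not in (0, 1):
            raise ValueError(f"vent_status must be 0 or 1, got {self.vent_status}")
        for name in VITAL_FEATURES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for {name}: {v}")

    def to_vector(self) -> np.ndarray:
        """Return the state as a length-13 float vector (feature order fixed)."""
        return np.array([getattr(self, n) for n in STATE_FEATURES], dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "PatientState":
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (13,):
            raise ValueError(f"expected a length-13 vector, got shape {vec.shape}")
        kwargs = {n: float(v) for n, v in zip(VITAL_FEATURES, vec[:12])}
        return cls(**kwargs, vent_status=int(vec[12]))


@dataclass(frozen=True)
class SedationState:
    """14-dimensional state for the sedation MDP: patient state + ventilation action."""

    base: PatientState
    vent_action_taken: int

    def __post_init__(self) -> None:
        if self.vent_action_taken not in (0, 1):
            raise ValueError("vent_action_taken must be 0 or 1")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.base.to_vector(), [float(self.vent_action_taken)]]
        )


@dataclass(frozen=True)
class CompositeAction:
    """Joint action: ventilation decision and sedative dose bin.

    ``vent``: 0 = keep the patient on the ventilator, 1 = wean.
    ``sedative_bin``: propofol dose level in {0, 1, 2, 3} (0 = lightest).
    """

    vent: int
    sedative_bin: int

    def __post_init__(self) -> None:
        if self.vent not in (0, 1):
            raise ValueError(f"vent must be 0 or 1, got {self.vent}")
        if self.sedative_bin not in (0, 1, 2, 3):
            raise ValueError(f"sedative_bin must be in 0..3, got {self.sedative_bin}")

    @property
    def index(self) -> int:
        """Flat index in the 8-element joint action space (vent-major order)."""
        return self.vent * 4 + self.sedative_bin

    @classmethod
    def from_index(cls, idx: int) -> "CompositeAction":
        if not 0 <= idx < 8:
            raise ValueError(f"composite action index out of range: {idx}")
        return cls(vent=idx // 4, sedative_bin=idx % 4)


@dataclass(frozen=True)
class RewardBreakdown:
    """Additive decomposition of the per-step reward.

    ``total`` is a derived property, so the identity
    ``total == r_vitals + r_vent_off + r_vent_on`` holds exactly by
    construction.
    """

    r_vitals: float
    r_vent_off: float
    r_vent_on: float

    @property
    def total(self) -> float:
        return self.r_vitals + self.r_vent_off + self.r_vent_on

    @classmethod
    def from_total(cls, total: float) -> "RewardBreakdown":
        """Wrap a bare total (e.g. read from file) when components are unknown.

        The total is stored in ``r_vitals``; only ``total`` is meaningful on
        such an instance.
        """
        return cls(r_vitals=float(total), r_vent_off=0.0, r_vent_on=0.0)


@dataclass(frozen=True)
class RewardConfig:
    """Constants of the decomposed reward, all auditable and overridable.

    Parameters
    ----------
    w_vitals
        Weight on the in-range fraction of vitals (unitless).
    bonus_success
        Bonus for a weaning action not followed by reintubation within
        ``window_steps``.
    penalty_reintubation
        Penalty (subtracted) when a weaning action is followed by
        reintubation within the window.
    window_steps
        Reintubation look-ahead window in 10-minute steps; the default of
        288 steps corresponds to the 48 h horizon clinicians use to call a
        wean failed.
    cost_per_step
        Cost charged for each step the patient spends on the ventilator.
    vital_ranges
        Mapping feature name -> (low, high) normal range. Every key must be
        one of the 12 vital features.
    """

    w_vitals: float = 1.0
    bonus_success: float = 10.0
    penalty_reintubation: float = 10.0
    window_steps: int = 288
    cost_per_step: float = 0.5
    vital_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(NORMAL_RANGES)
    )

    def __post_init__(self) -> None:
        for name in self.vital_ranges:
            if name not in VITAL_FEATURES:
                raise KeyError(f"unknown vital in reward config ranges: {name!r}")


class Stratum(str, Enum):
    """Test-set strata used for stratified reporting."""

    EXPERT = "expert"
    SINGLE_INTUBATION = "single_intubation"
    MULTIPLE_INTUBATION = "multiple_intubation"


@dataclass(frozen=True)
class Transition:
    """One (s, a, r, s') step with the clinician's action label."""

    state: PatientState
    action: CompositeAction
    reward: RewardBreakdown
    next_state: PatientState
    terminal: bool
    clinician_action: CompositeAction


@dataclass
class Trajectory:
    """All transitions of one ICU admission, in 10-minute order."""

    admission_id: str
    transitions: list[Transition]
    stratum: Stratum | None = None
    expert: bool = False

    def __len__(self) -> int:
        return len(self.transitions)

    @property
    def rewards(self) -> np.ndarray:
        return np.array([tr.reward.total for tr in self.transitions], dtype=np.float64)

    @property
    def n_intubations(self) -> int:
        """Number of intubation events: on-vent at admission counts as one,
        plus every off->on flip of the ventilation status."""
        status = [tr.state.vent_status for tr in self.transitions]
        status.append(self.transitions[-1].next_state.vent_status)
        n = 1 if status[0] == 1 else 0
        for prev, cur in zip(status, status[1:]):
            if prev == 0 and cur == 1:
                n += 1
        return n


def in_range_fraction(state: PatientState, ranges: Mapping[str, tuple[float, float]]) -> float:
    """Fraction of the configured vitals lying inside their [low, high] range."""
    if not ranges:
        return 0.0
    hits = 0
    for name, (lo, hi) in ranges.items():
        if name not in VITAL_FEATURES:
            raise KeyError(f"unknown vital in ranges: {name!r}")
        if lo <= getattr(state, name) <= hi:
            hits += 1
    return hits / len(ranges)


def compute_reward(
    state: PatientState,
    action: CompositeAction,
    next_state: PatientState,
    cfg: RewardConfig,
    *,
    reintubation_follows: bool = False,
) -> RewardBreakdown:
    """Decomposed reward for one transition.

    ``reintubation_follows`` must be supplied by the caller from look-ahead
    over the trajectory: True iff a weaning action taken now is followed by
    reintubation within ``cfg.window_steps`` steps. It is ignored when the
    action keeps the patient ventilated.

    The wean bonus/penalty applies to the weaning *event* — a wean action
    taken while the patient is still on the ventilator — not to every
    subsequent step spent off it.

    The function is pure: identical arguments always yield the identical
    breakdown.
    """
    r_vitals = cfg.w_vitals * in_range_fraction(next_state, cfg.vital_ranges)
    if action.vent == 1 and state.vent_status == 1:
        r_vent_off = (
            -cfg.penalty_reintubation if reintubation_follows else cfg.bonus_success
        )
    else:
        r_vent_off = 0.0
    r_vent_on = -cfg.cost_per_step if next_state.vent_status == 1 else 0.0
    return RewardBreakdown(r_vitals=r_vitals, r_vent_off=r_vent_off, r_vent_on=r_vent_on)


def discounted_return(traj: Trajectory | Iterable[float], gamma: float) -> float:
    """Discounted return  sum_t  gamma^t * r_t  along one trajectory.

    Accepts either a :class:`Trajectory` or a bare reward sequence.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    rewards = traj.rewards if isinstance(traj, Trajectory) else np.asarray(list(traj), dtype=np.float64)
    if rewards.size == 0:
        return 0.0
    discounts = gamma ** np.arange(rewards.size)
    return float(np.dot(discounts, rewards))


def encode_action(action: CompositeAction) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode the two action components separately.

    Bit order: index 0 is the first category (vent = keep; sedative bin 0).
    Returns ``(length-2 vent block, length-4 sedative block)``, each with
    exactly one active bit.
    """
    vent = np.zeros(2, dtype=np.float64)
    vent[action.vent] = 1.0
    sed = np.zeros(4, dtype=np.float64)
    sed[action.sedative_bin] = 1.0
    return vent, sed


def decode_action(vent_onehot: Sequence[float], sed_onehot: Sequence[float]) -> CompositeAction:
    """Inverse of :func:`encode_action` (argmax per block)."""
    vent = np.asarray(vent_onehot)
    sed = np.asarray(sed_onehot)
    if vent.shape != (2,) or sed.shape != (4,):
        raise ValueError("expected length-2 and length-4 one-hot blocks")
    return CompositeAction(vent=int(np.argmax(vent)), sedative_bin=int(np.argmax(sed)))


def build_sedation_state(s: PatientState, vent_action: int) -> SedationState:
    """Augment a patient state with the ventilation action just taken (14-dim)."""
    return SedationState(base=s, vent_action_taken=int(vent_action))


def stratify(trajectories: Sequence[Trajectory]) -> dict[Stratum, list[Trajectory]]:
    """Partition trajectories into the three reporting strata.

    Precedence: an expert (noise-free-label) trajectory goes to the expert
    stratum regardless of its intubation count; the remainder split by
    whether they contain >= 2 intubation events. Every trajectory lands in
    exactly one stratum and its ``stratum`` attribute is set in place.
    """
    out: dict[Stratum, list[Trajectory]] = {s: [] for s in Stratum}
    for traj in trajectories:
        if traj.expert:
            s = Stratum.EXPERT
        elif traj.n_intubations >= 2:
            s = Stratum.MULTIPLE_INTUBATION
        else:
            s = Stratum.SINGLE_INTUBATION
        traj.stratum = s
        out[s].append(traj)
    return out
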