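"""Offline actor-critic training with optional clinician supervision.

The data is a fixed cohort of clinician-labeled trajectories (no live
environment): an *episode* is one shuffled pass over the training
transitions in minibatches. Per minibatch,

1. the TD target ``y = r + gamma * Q_tar(s', mu(s'))`` is formed with the
   *target* critic and the current actor's greedy action at the successor
   state (``y = r`` at terminal transitions or when gamma = 0);
2. the critic takes one gradient step down the mean squared TD loss;
3. the actor takes one gradient step up the blended objective
   ``J = (1 - eps) * J_RL + eps * (-J_SL)``, where J_RL is the
   TD-error-weighted log-likelihood of the logged actions and J_SL the
   cross-entropy toward the clinician labels.

``algorithm="ac"`` is the plain actor-critic (reinforcement term only) and
``algorithm="bc"`` pure behavior cloning (supervised term only); they are
the eps = 0 and eps = 1 degeneracies of the blend and follow the same loop
with the same random-number stream, so their parameter trajectories match
the corresponding SAC runs exactly.

States are standardized (per-feature z-score fitted on the training split)
before entering any network; the scaler is part of the trained policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import networks as nets
from .mdp import Trajectory
from .networks import Params

__all__ = [
    "TrainConfig",
    "TrainResult",
    "Standardizer",
    "StageArrays",
    "build_stage_arrays",
    "td_target",
    "critic_update",
    "actor_update",
    "sync_target",
    "train",
]

STAGE_DIMS = {"vent": (13, 2), "sed": (14, 4)}


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``epsilon`` blends reinforcement and supervision in the actor objective
    (0 = pure RL, 1 = pure behavior cloning); it is forced to 0 for
    ``algorithm="ac"`` and to 1 for ``algorithm="bc"``.
    """

    stage: str = "vent"                 # "vent" or "sed"
    algorithm: str = "sac"              # "sac", "ac" or "bc"
    epsilon: float = 0.5
    alpha_actor: float = 3e-3
    alpha_critic: float = 1e-3
    gamma: float = 0.95
    target_sync_every: int = 100
    batch_size: int = 32
    n_episodes: int = 60
    seed: int = 0
    holdout_fraction: float = 0.2
    eval_batch: int = 512
    bootstrap: str = "greedy"           # "greedy" or "expected" successor action
    dose_map: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    label_source: str = "labels"        # "labels" or "supervisor"
    record_params: bool = False

    def __post_init__(self) -> None:
        if self.stage not in STAGE_DIMS:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.algorithm not in ("sac", "ac", "bc"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.alpha_actor <= 0 or self.alpha_critic <= 0:
            raise ValueError("learning rates must be positive")
        if self.label_source not in ("labels", "supervisor"):
            raise ValueError(f"unknown label_source {self.label_source!r}")

    @property
    def effective_epsilon(self) -> float:
        return {"ac": 0.0, "bc": 1.0}.get(self.algorithm, self.epsilon)


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on the training split."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        std = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(std < 1e-8, 1.0, std))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))


@dataclass
class StageArrays:
    """Flattened transition arrays for one MDP stage."""

    states: np.ndarray          # (n, d) raw (unstandardized)
    actions: np.ndarray         # (n,) logged/clinician action class
    rewards: np.ndarray         # (n,)
    next_states: np.ndarray     # (n, d)
    terminal: np.ndarray        # (n,) bool

    def __len__(self) -> int:
        return len(self.actions)


def build_stage_arrays(trajectories: Sequence[Trajectory], stage: str) -> StageArrays:
    """Flatten trajectories into per-stage training arrays.

    Ventilation stage: 13-dim states, binary wean action. Sedation stage:
    14-dim states (state + the clinician's ventilation action at that step),
    4-class sedative bin; the successor state carries the next step's
    ventilation action (the terminal successor reuses the current one — it
    never enters a bootstrapped target).
    """
    if stage not in STAGE_DIMS:
        raise ValueError(f"unknown stage {stage!r}")
    S, A, R, S2, T = [], [], [], [], []
    for traj in trajectories:
        trs = traj.transitions
        for t, tr in enumerate(trs):
            if stage == "vent":
                s = tr.state.to_vector()
                s2 = tr.next_state.to_vector()
                a = tr.clinician_action.vent
            else:
                s = np.append(tr.state.to_vector(), float(tr.clinician_action.vent))
                next_vent = (
                    trs[t + 1].clinician_action.vent
                    if t + 1 < len(trs)
                    else tr.clinician_action.vent
                )
                s2 = np.append(tr.next_state.to_vector(), float(next_vent))
                a = tr.clinician_action.sedative_bin
            S.append(s)
            A.append(a)
            R.append(tr.reward.total)
            S2.append(s2)
            T.append(tr.terminal)
    return StageArrays(
        states=np.array(S),
        actions=np.array(A, dtype=np.intp),
        rewards=np.array(R, dtype=np.float64),
        next_states=np.array(S2),
        terminal=np.array(T, dtype=bool),
    )


def _onehot(classes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(classes), k))
    out[np.arange(len(classes)), classes] = 1.0
    return out


def _bootstrap_q(
    actor: Params, critic_tar: Params, s_next: np.ndarray, n_actions: int, mode: str
) -> np.ndarray:
    """Q_tar(s', mu(s')): greedy realization of the actor at the successor,
    or the expectation over the softmax policy when mode='expected'."""
    probs = nets.actor_forward(actor, s_next)
    if mode == "greedy":
        a_star = np.argmax(probs, axis=1)
        return nets.critic_forward(critic_tar, s_next, _onehot(a_star, n_actions))
    qs = np.column_stack(
        [
            nets.critic_forward(
                critic_tar, s_next, _onehot(np.full(len(s_next), a, dtype=np.intp), n_actions)
            )
            for a in range(n_actions)
        ]
    )
    return np.sum(probs * qs, axis=1)


def td_target(
    r: float,
    s_next: np.ndarray,
    actor: Params,
    critic_tar: Params,
    gamma: float,
    terminal: bool,
    n_actions: int | None = None,
    bootstrap: str = "greedy",
) -> float:
    """Scalar TD target y = r + gamma * Q_tar(s', mu(s')); y = r at terminals."""
    if terminal or gamma == 0.0:
        return float(r)
    if n_actions is None:
        n_actions = int(actor["W2"].shape[1])
    q = _bootstrap_q(actor, critic_tar, np.atleast_2d(s_next), n_actions, bootstrap)
    return float(r + gamma * q[0])


def _td_targets_batch(
    rewards: np.ndarray,
    s_next: np.ndarray,
    terminal: np.ndarray,
    actor: Params,
    critic_tar: Params,
    gamma: float,
    n_actions: int,
    bootstrap: str,
) -> np.ndarray:
    if gamma == 0.0:
        return rewards.copy()
    q = _bootstrap_q(actor, critic_tar, s_next, n_actions, bootstrap)
    return rewards + gamma * q * (~terminal)


def critic_update(
    critic: Params,
    states: np.ndarray,
    action_onehots: np.ndarray,
    targets: np.ndarray,
    alpha: float,
) -> tuple[Params, float]:
    """One SGD step down the mean squared TD loss; returns (new params, loss before)."""
    if len(states) == 0:
        raise ValueError("empty batch")
    loss, grads = nets.critic_loss(critic, states, action_onehots, targets)
    return nets.step(critic, grads, alpha), loss


def actor_update(
    actor: Params,
    states: np.ndarray,
    taken_actions: np.ndarray,
    td_errors: np.ndarray,
    labels: np.ndarray | None,
    cfg: TrainConfig,
) -> Params:
    """One SGD step up the blended actor objective."""
    mode = cfg.algorithm
    _, grads = nets.actor_objective(
        actor, states, taken_actions, td_errors, labels, cfg.effective_epsilon, mode=mode
    )
    return nets.step(actor, grads, cfg.alpha_actor, ascend=True)


def sync_target(critic: Params) -> Params:
    """Hard copy of the critic parameters into the target network."""
    return nets.copy_params(critic)


def pretrain_supervisor(
    states: np.ndarray,
    labels: np.ndarray,
    n_actions: int,
    seed: int,
    epochs: int = 30,
    lr: float = 3e-3,
    batch_size: int = 32,
) -> Params:
    """Fit the 9-hidden-unit supervisor classifier on clinician labels.

    Its argmax predictions can then stand in for the raw labels in the
    supervised term of the actor objective (``label_source="supervisor"``).
    """
    params = nets.supervisor_init(states.shape[1], n_actions, seed)
    rng = np.random.default_rng(seed)
    n = len(states)
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            b = perm[start : start + batch_size]
            _, grads = nets.supervised_loss(params, states[b], labels[b])
            params = nets.step(params, grads, lr)
    return params


@dataclass
class TrainResult:
    """Trained policy plus everything needed to evaluate or resume it."""

    actor: Params
    critic: Params
    critic_target: Params
    scaler: Standardizer
    curve: pd.DataFrame
    cfg: TrainConfig
    param_history: list[Params] = field(default_factory=list)

    def greedy(self, raw_states: np.ndarray) -> np.ndarray:
        """Greedy action classes for raw (unstandardized) states."""
        return nets.greedy_actions(self.actor, self.scaler.transform(raw_states))

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        manifest = {"scaler": self.scaler.to_dict(), "stage": self.cfg.stage,
                    "algorithm": self.cfg.algorithm, "seed": self.cfg.seed,
                    "epsilon": self.cfg.effective_epsilon}
        nets.save_params(self.actor, out / "actor", manifest)
        nets.save_params(self.critic, out / "critic", manifest)
        self.curve.to_csv(out / "learning_curve.csv", index=False)


def _split_holdout(
    trajectories: Sequence[Trajectory], fraction: float, rng: np.random.Generator
) -> tuple[list[Trajectory], list[Trajectory]]:
    idx = rng.permutation(len(trajectories))
    n_hold = int(round(fraction * len(trajectories)))
    hold = [trajectories[i] for i in idx[:n_hold]]
    tr = [trajectories[i] for i in idx[n_hold:]]
    return tr, hold


def _dose_mse(pred: np.ndarray, label: np.ndarray, dose_map: Sequence[float]) -> float:
    dm = np.asarray(dose_map, dtype=np.float64)
    return float(np.mean((dm[pred] - dm[label]) ** 2))


def train(trajectories: Sequence[Trajectory], cfg: TrainConfig) -> TrainResult:
    """Run the offline learning loop on a labeled cohort.

    Returns the trained actor/critic plus a per-episode learning curve with
    columns ``episode, mean_q, ar, mse, critic_loss`` — mean Q over a fixed
    evaluation batch, accuracy rate and (sedation only) dose MSE on the
    held-out admissions, and the mean critic loss of the episode.
    Fully reproducible from ``cfg.seed``.
    """
    if len(trajectories) == 0:
        raise ValueError("empty dataset")
    d_state, n_actions = STAGE_DIMS[cfg.stage]
    rng = np.random.default_rng(cfg.seed)

    train_trajs, hold_trajs = _split_holdout(trajectories, cfg.holdout_fraction, rng)
    if not train_trajs:
        raise ValueError("holdout fraction leaves no training admissions")
    data = build_stage_arrays(train_trajs, cfg.stage)
    hold = build_stage_arrays(hold_trajs, cfg.stage) if hold_trajs else data

    scaler = Standardizer.fit(data.states)
    S = scaler.transform(data.states)
    S2 = scaler.transform(data.next_states)
    S_hold = scaler.transform(hold.states)
    A_oh = _onehot(data.actions, n_actions)

    actor = nets.actor_init(d_state, n_actions, cfg.seed + 1)
    critic = nets.critic_init(d_state, n_actions, cfg.seed + 2)
    critic_tar = sync_target(critic)

    if cfg.label_source == "supervisor":
        supervisor = pretrain_supervisor(S, data.actions, n_actions, cfg.seed + 3)
        sl_labels = np.argmax(nets.actor_forward(supervisor, S), axis=1)
    else:
        sl_labels = data.actions

    n = len(data)
    eval_idx = np.arange(min(cfg.eval_batch, n))
    steps_since_sync = 0
    records = []
    history: list[Params] = []

    for episode in range(cfg.n_episodes):
        perm = rng.permutation(n)
        ep_losses = []
        for start in range(0, n, cfg.batch_size):
            b = perm[start : start + cfg.batch_size]
            y = _td_targets_batch(
                data.rewards[b], S2[b], data.terminal[b],
                actor, critic_tar, cfg.gamma, n_actions, cfg.bootstrap,
            )
            q_pred = nets.critic_forward(critic, S[b], A_oh[b])
            td_err = y - q_pred
            critic, loss = critic_update(critic, S[b], A_oh[b], y, cfg.alpha_critic)
            ep_losses.append(loss)
            steps_since_sync += 1
            if steps_since_sync >= cfg.target_sync_every:
                critic_tar = sync_target(critic)
                steps_since_sync = 0
            actor = actor_update(actor, S[b], data.actions[b], td_err, sl_labels[b], cfg)

        mean_q = float(
            np.mean(nets.critic_forward(critic, S[eval_idx], A_oh[eval_idx]))
        )
        pred_hold = nets.greedy_actions(actor, S_hold)
        ar = float(np.mean(pred_hold == hold.actions))
        mse = (
            _dose_mse(pred_hold, hold.actions, cfg.dose_map)
            if cfg.stage == "sed"
            else float("nan")
        )
        records.append(
            {"episode": episode, "mean_q": mean_q, "ar": ar, "mse": mse,
             "critic_loss": float(np.mean(ep_losses))}
        )
        if cfg.record_params:
            history.append(nets.copy_params(actor))

    curve = pd.DataFrame.from_records(
        records, columns=["episode", "mean_q", "ar", "mse", "critic_loss"]
    )
    return TrainResult(
        actor=actor, critic=critic, critic_target=critic_tar,
        scaler=scaler, curve=curve, cfg=cfg, param_history=history,
    )
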