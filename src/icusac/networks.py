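"""Actor, Critic and Supervisor function approximators.

All three are three-layer perceptrons, small enough that forward and backward
passes are written directly in numpy:

* **Actor** — state in, softmax over action classes out (2 for the
  ventilation decision, 4 for the sedative bin), 20 rectifier hidden units.
* **Critic** — state concatenated with the one-hot action in, a single
  linear output Q(s, a), 20 rectifier hidden units.
* **Supervisor** — a 9-hidden-unit softmax classifier over the same action
  classes; it can be pre-trained on clinician labels to stand in for raw
  labels in the supervised term of the actor objective.

Every analytic gradient here is checked against central finite differences
in the test suite.

Parameters are plain ``{"W1", "b1", "W2", "b2"}`` dicts of float64 arrays;
the functions are pure (no in-place mutation of inputs).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "init_params",
    "actor_init",
    "critic_init",
    "supervisor_init",
    "actor_forward",
    "critic_forward",
    "greedy_actions",
    "supervised_loss",
    "actor_objective",
    "critic_loss",
    "save_params",
    "load_params",
]

Params = dict[str, np.ndarray]

ACTOR_HIDDEN = 20
CRITIC_HIDDEN = 20
SUPERVISOR_HIDDEN = 9


def init_params(seed: int, layer_sizes: tuple[int, int, int]) -> Params:
    """He-scaled random initialization, reproducible from the seed.

    ``layer_sizes`` is (input, hidden, output); weights are drawn
    N(0, sqrt(2/fan_in)) and biases start at zero.
    """
    d_in, hidden, d_out = layer_sizes
    rng = np.random.default_rng(seed)
    return {
        "W1": rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, hidden)),
        "b1": np.zeros(hidden),
        "W2": rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, d_out)),
        "b2": np.zeros(d_out),
    }


def actor_init(state_dim: int, n_actions: int, seed: int) -> Params:
    return init_params(seed, (state_dim, ACTOR_HIDDEN, n_actions))


def critic_init(state_dim: int, n_actions: int, seed: int) -> Params:
    return init_params(seed, (state_dim + n_actions, CRITIC_HIDDEN, 1))


def supervisor_init(state_dim: int, n_actions: int, seed: int) -> Params:
    return init_params(seed, (state_dim, SUPERVISOR_HIDDEN, n_actions))


def _check_dim(x: np.ndarray, params: Params, who: str) -> None:
    if x.shape[-1] != params["W1"].shape[0]:
        raise ValueError(
            f"{who}: input dimension {x.shape[-1]} does not match "
            f"network input {params['W1'].shape[0]}"
        )


def _hidden(params: Params, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z1 = x @ params["W1"] + params["b1"]
    return z1, np.maximum(z1, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def actor_forward(params: Params, states: np.ndarray) -> np.ndarray:
    """Action-probability vector(s) of the softmax policy.

    Accepts a single state (1-D) or a batch (2-D); output matches.
    """
    states = np.asarray(states, dtype=np.float64)
    single = states.ndim == 1
    x = states[None, :] if single else states
    _check_dim(x, params, "actor_forward")
    _, a1 = _hidden(params, x)
    probs = _softmax(a1 @ params["W2"] + params["b2"])
    return probs[0] if single else probs


def greedy_actions(params: Params, states: np.ndarray) -> np.ndarray:
    """Greedy (argmax-probability) action per state; ties break to the lowest index."""
    probs = actor_forward(params, np.atleast_2d(np.asarray(states, dtype=np.float64)))
    return np.argmax(probs, axis=1)


def critic_forward(params: Params, states: np.ndarray, action_onehot: np.ndarray) -> np.ndarray | float:
    """Q(s, a) for state(s) and one-hot encoded action(s); linear output head."""
    states = np.asarray(states, dtype=np.float64)
    action_onehot = np.asarray(action_onehot, dtype=np.float64)
    single = states.ndim == 1
    x = np.concatenate(
        [np.atleast_2d(states), np.atleast_2d(action_onehot)], axis=1
    )
    _check_dim(x, params, "critic_forward")
    _, a1 = _hidden(params, x)
    q = (a1 @ params["W2"] + params["b2"])[:, 0]
    return float(q[0]) if single else q


def _backprop(params: Params, x: np.ndarray, z1: np.ndarray, a1: np.ndarray,
              dlogits: np.ndarray) -> Params:
    """Gradients of a scalar objective wrt params, given d(objective)/d(logits)."""
    da1 = dlogits @ params["W2"].T
    dz1 = da1 * (z1 > 0.0)
    return {
        "W1": x.T @ dz1,
        "b1": dz1.sum(axis=0),
        "W2": a1.T @ dlogits,
        "b2": dlogits.sum(axis=0),
    }


def supervised_loss(params: Params, states: np.ndarray, labels: np.ndarray) -> tuple[float, Params]:
    """Mean cross-entropy between the softmax prediction and one-hot labels.

    Returns ``(loss, gradient)`` where the gradient is of the loss (to be
    descended). The loss is >= 0 and reaches 0 only on a perfectly
    concentrated correct prediction.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    _check_dim(states, params, "supervised_loss")
    n, k = states.shape[0], params["W2"].shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"label out of range for {k} classes")
    z1, a1 = _hidden(params, states)
    probs = _softmax(a1 @ params["W2"] + params["b2"])
    eps = 1e-300  # guards log(0) only; softmax output is strictly positive
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (probs - onehot) / n
    return loss, _backprop(params, states, z1, a1, dlogits)


def actor_objective(
    params: Params,
    states: np.ndarray,
    taken_actions: np.ndarray,
    td_errors: np.ndarray,
    labels: np.ndarray | None,
    epsilon: float,
    mode: str = "sac",
) -> tuple[float, Params]:
    """Blended actor objective J = (1-eps)*J_RL + eps*(-J_SL) and its gradient.

    J_RL is the TD-error-weighted log-likelihood of the taken actions
    (mean over the batch) — ascending it reinforces actions the critic
    found better than expected. J_SL is the cross-entropy toward the
    clinician labels, so -J_SL pulls the policy toward the clinician.

    ``mode`` selects the estimator: ``"sac"`` blends by epsilon, ``"ac"``
    is the pure reinforcement term, ``"bc"`` the pure supervised term; the
    latter two take separate code paths so the blend degeneracies
    (eps=0 <-> ac, eps=1 <-> bc) are genuine cross-checks, not tautologies.

    Returns ``(J, gradient of J)``; the gradient is to be *ascended*.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    taken_actions = np.atleast_1d(np.asarray(taken_actions, dtype=np.intp))
    td_errors = np.atleast_1d(np.asarray(td_errors, dtype=np.float64))
    _check_dim(states, params, "actor_objective")
    n = states.shape[0]
    z1, a1 = _hidden(params, states)
    probs = _softmax(a1 @ params["W2"] + params["b2"])
    logp = np.log(probs + 1e-300)

    def rl_terms() -> tuple[float, np.ndarray]:
        j = float(np.mean(td_errors * logp[np.arange(n), taken_actions]))
        e_a = np.zeros_like(probs)
        e_a[np.arange(n), taken_actions] = 1.0
        return j, (td_errors[:, None] * (e_a - probs)) / n

    def sl_terms() -> tuple[float, np.ndarray]:
        lab = np.atleast_1d(np.asarray(labels, dtype=np.intp))
        j = float(np.mean(logp[np.arange(n), lab]))  # -J_SL = mean log p(label)
        e_y = np.zeros_like(probs)
        e_y[np.arange(n), lab] = 1.0
        return j, (e_y - probs) / n

    if mode == "ac":
        j, dlogits = rl_terms()
    elif mode == "bc":
        j, dlogits = sl_terms()
    elif mode == "sac":
        j_rl, g_rl = rl_terms()
        j_sl, g_sl = sl_terms()
        j = (1.0 - epsilon) * j_rl + epsilon * j_sl
        dlogits = (1.0 - epsilon) * g_rl + epsilon * g_sl
    else:
        raise ValueError(f"unknown actor objective mode {mode!r}")
    return j, _backprop(params, states, z1, a1, dlogits)


def critic_loss(
    params: Params,
    states: np.ndarray,
    action_onehots: np.ndarray,
    targets: np.ndarray,
) -> tuple[float, Params]:
    """Mean squared TD loss J(w) = mean (Q_w(s,a) - y)^2 and its gradient.

    Targets are treated as constants (no gradient flows through y).
    Returns ``(loss, gradient of loss)``; the gradient is to be descended.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.float64))
    action_onehots = np.atleast_2d(np.asarray(action_onehots, dtype=np.float64))
    targets = np.atleast_1d(np.asarray(targets, dtype=np.float64))
    x = np.concatenate([states, action_onehots], axis=1)
    _check_dim(x, params, "critic_loss")
    n = x.shape[0]
    z1, a1 = _hidden(params, x)
    q = (a1 @ params["W2"] + params["b2"])[:, 0]
    err = q - targets
    loss = float(np.mean(err**2))
    dlogits = (2.0 * err / n)[:, None]
    return loss, _backprop(params, x, z1, a1, dlogits)


def step(params: Params, grads: Params, lr: float, ascend: bool = False) -> Params:
    """One SGD step; returns new params (inputs untouched)."""
    sign = 1.0 if ascend else -1.0
    return {k: params[k] + sign * lr * grads[k] for k, v in params.items()}


def copy_params(params: Params) -> Params:
    return {k: v.copy() for k, v in params.items()}


def params_equal(a: Mapping[str, np.ndarray], b: Mapping[str, np.ndarray]) -> bool:
    return set(a) == set(b) and all(np.array_equal(a[k], b[k]) for k in a)


def save_params(params: Params, path: str | Path, manifest: dict | None = None) -> None:
    """Checkpoint as a flat key->array archive plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **params)
    meta = dict(manifest or {})
    meta["arrays"] = {k: list(v.shape) for k, v in params.items()}
    (path / "manifest.json").write_text(json.dumps(meta, indent=2))


def load_params(path: str | Path) -> tuple[Params, dict]:
    path = Path(path)
    with np.load(path / "params.npz") as archive:
        params = {k: archive[k].copy() for k in archive.files}
    manifest = json.loads((path / "manifest.json").read_text())
    return params, manifest
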