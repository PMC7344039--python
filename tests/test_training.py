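"""TD targets, critic/actor updates, blend linearity and the offline loop."""

import numpy as np
import pytest

from icusac import networks as nets
from icusac.training import (
    StageArrays,
    TrainConfig,
    actor_update,
    build_stage_arrays,
    critic_update,
    sync_target,
    td_target,
    train,
)


def constant_critic(d_state, n_actions, value):
    """A critic whose output equals `value` for every input."""
    p = {
        "W1": np.zeros((d_state + n_actions, 20)),
        "b1": np.zeros(20),
        "W2": np.zeros((20, 1)),
        "b2": np.array([value]),
    }
    return p


class TestTdTarget:
    def test_gamma_zero_kills_bootstrap(self):
        actor = nets.actor_init(13, 2, seed=0)
        tar = nets.critic_init(13, 2, seed=1)
        y = td_target(3.0, np.ones(13), actor, tar, gamma=0.0, terminal=False)
        assert y == 3.0

    def test_terminal_target_is_reward(self):
        actor = nets.actor_init(13, 2, seed=0)
        tar = nets.critic_init(13, 2, seed=1)
        y = td_target(-2.5, np.ones(13), actor, tar, gamma=0.95, terminal=True)
        assert y == -2.5

    def test_hand_evaluated_bootstrap(self):
        """y = 1 + 0.9 * 2 = 2.8 with a critic pinned at Q = 2."""
        actor = nets.actor_init(13, 2, seed=0)
        tar = constant_critic(13, 2, 2.0)
        y = td_target(1.0, np.ones(13), actor, tar, gamma=0.9, terminal=False)
        assert y == pytest.approx(2.8)


class TestCriticUpdate:
    def test_perfect_fit_gives_zero_gradient(self):
        critic = constant_critic(3, 2, 0.0)
        S = np.ones((4, 3))
        A = np.eye(2)[[0, 1, 0, 1]]
        new, loss = critic_update(critic, S, A, np.zeros(4), alpha=0.1)
        assert loss == 0.0
        assert nets.params_equal(new, critic)

    def test_empty_batch_rejected(self):
        critic = nets.critic_init(3, 2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            critic_update(critic, np.empty((0, 3)), np.empty((0, 2)), np.empty(0), 0.1)

    def test_repeated_updates_fit_one_transition(self):
        """Loss on a single fixed transition drops below 1e-4 within 5000 steps."""
        rng = np.random.default_rng(13)
        critic = nets.critic_init(4, 2, seed=14)
        s = rng.normal(size=(1, 4))
        a = np.array([[1.0, 0.0]])
        y = np.array([1.7])
        loss = np.inf
        for _ in range(5000):
            critic, loss = critic_update(critic, s, a, y, alpha=1e-2)
            if loss < 1e-4:
                break
        assert loss < 1e-4


class TestBlendLinearity:
    def test_update_is_affine_in_epsilon(self):
        rng = np.random.default_rng(15)
        theta = nets.actor_init(5, 2, seed=16)
        S = rng.normal(size=(8, 5))
        A = rng.integers(0, 2, size=8)
        delta = rng.normal(scale=2.0, size=8)

        def delta_theta(eps):
            cfg = TrainConfig(stage="vent", algorithm="sac", epsilon=eps)
            new = actor_update(theta, S, A, delta, A, cfg)
            return {k: new[k] - theta[k] for k in theta}

        d0, d1 = delta_theta(0.0), delta_theta(1.0)
        for eps in (0.25, 0.5, 0.75):
            de = delta_theta(eps)
            for k in theta:
                np.testing.assert_allclose(
                    de[k], (1 - eps) * d0[k] + eps * d1[k], atol=1e-12
                )

    def test_pure_mode_updates_match_blend_endpoints(self):
        rng = np.random.default_rng(17)
        theta = nets.actor_init(5, 2, seed=18)
        S = rng.normal(size=(6, 5))
        A = rng.integers(0, 2, size=6)
        delta = rng.normal(size=6)
        sac0 = actor_update(theta, S, A, delta, A, TrainConfig(algorithm="sac", epsilon=0.0))
        ac = actor_update(theta, S, A, delta, A, TrainConfig(algorithm="ac"))
        assert nets.params_equal(sac0, ac)
        sac1 = actor_update(theta, S, A, delta, A, TrainConfig(algorithm="sac", epsilon=1.0))
        bc = actor_update(theta, S, A, delta, A, TrainConfig(algorithm="bc"))
        assert nets.params_equal(sac1, bc)


class TestSyncTarget:
    def test_copy_is_exact_and_independent(self):
        critic = nets.critic_init(13, 2, seed=19)
        tar = sync_target(critic)
        assert nets.params_equal(tar, critic)
        critic["W1"][0, 0] += 1.0
        assert not nets.params_equal(tar, critic)


class TestStageArrays:
    def test_shapes_and_dims(self, small_cohort):
        vent = build_stage_arrays(small_cohort, "vent")
        sed = build_stage_arrays(small_cohort, "sed")
        assert vent.states.shape[1] == 13
        assert sed.states.shape[1] == 14
        assert len(vent) == len(sed) == sum(len(t) for t in small_cohort)
        assert set(np.unique(vent.actions)) <= {0, 1}
        assert set(np.unique(sed.actions)) <= {0, 1, 2, 3}
        # one terminal per admission
        assert vent.terminal.sum() == len(small_cohort)

    def test_sedation_state_carries_vent_action(self, small_cohort):
        sed = build_stage_arrays(small_cohort, "sed")
        k = 0
        for traj in small_cohort:
            for tr in traj.transitions:
                assert sed.states[k, 13] == tr.clinician_action.vent
                k += 1


class TestTrainLoop:
    def test_curve_has_one_row_per_episode(self, small_cohort):
        res = train(small_cohort, TrainConfig(n_episodes=5, seed=0))
        assert list(res.curve["episode"]) == list(range(5))
        assert res.curve[["mean_q", "ar", "critic_loss"]].notna().all().all()

    def test_seed_determinism(self, small_cohort):
        cfg = TrainConfig(n_episodes=3, seed=21)
        a = train(small_cohort, cfg)
        b = train(small_cohort, cfg)
        assert nets.params_equal(a.actor, b.actor)
        assert nets.params_equal(a.critic, b.critic)
        assert a.curve.equals(b.curve)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TrainConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError, match="epsilon"):
            TrainConfig(epsilon=1.5)
        with pytest.raises(ValueError, match="stage"):
            TrainConfig(stage="other")
        with pytest.raises(ValueError, match="algorithm"):
            TrainConfig(algorithm="ppo")

    def test_pretrained_supervisor_can_replace_labels(self, noise_free_cohort):
        """The 9-unit supervisor learns the clinician rule well enough that
        cloning its predictions still tracks the clinician closely."""
        from icusac.training import pretrain_supervisor
        from icusac.training import Standardizer

        arrays = build_stage_arrays(noise_free_cohort[:40], "vent")
        scaler = Standardizer.fit(arrays.states)
        S = scaler.transform(arrays.states)
        sup = pretrain_supervisor(S, arrays.actions, 2, seed=9)
        sup_acc = np.mean(np.argmax(nets.actor_forward(sup, S), axis=1) == arrays.actions)
        assert sup_acc > 0.9
        res = train(noise_free_cohort[:40], TrainConfig(
            algorithm="bc", n_episodes=20, seed=9, label_source="supervisor"))
        assert res.curve["ar"].iloc[-1] > 0.9

    def test_result_round_trips_through_save(self, small_cohort, tmp_path):
        res = train(small_cohort, TrainConfig(n_episodes=2, seed=1))
        res.save(tmp_path)
        loaded, manifest = nets.load_params(tmp_path / "actor")
        assert nets.params_equal(loaded, res.actor)
        assert manifest["stage"] == "vent"
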