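"""Tests of the reward-modulated Hebbian rules and eligibility traces."""

import numpy as np
import pytest
from scipy.special import softmax

from spikeplan import (
    Activation,
    EligibilityTrace,
    GridMazeTask,
    LearnConfig,
    NetworkParams,
    Potential,
    infinite_horizon_update,
    log_trajectory_prob,
    membrane_potential,
    offline_update,
    one_hot,
    online_update,
    sample_trajectory,
    step_gradient,
    trace_step,
    train_episodic,
    train_maze,
    trajectory_gradient,
    maze_params,
)
from spikeplan.plasticity import train_finite_offline

from conftest import random_params


def finite_difference_theta_grad(params, train, h=1e-5):
    """Central-difference gradient of log p(train) wrt Theta: the
    independent oracle for the Hebbian rule."""
    G = np.zeros_like(params.Theta)
    for k in range(params.K):
        for j in range(params.N):
            for sign in (+1, -1):
                Th = params.Theta.copy()
                Th[k, j] += sign * h
                G[k, j] += sign * log_trajectory_prob(train, params.with_theta(Th))
    return G / (2 * h)


class TestStepGradient:
    def test_expectation_matched_spikes_give_zero(self):
        rho = np.array([0.2, 0.3, 0.5])
        pot = Potential(u=np.log(rho), rho=rho, activation=Activation.SOFTMAX_WTA)
        G = step_gradient(rho, pot, np.ones(2))
        np.testing.assert_allclose(G, 0.0, atol=1e-15)

    def test_silent_context_gives_zero(self):
        rho = np.array([0.2, 0.8])
        pot = Potential(u=np.zeros(2), rho=rho, activation=Activation.SIGMOID)
        G = step_gradient(one_hot(0, 2), pot, np.zeros(3))
        np.testing.assert_allclose(G, 0.0)

    def test_locality_of_rows_and_columns(self):
        """G[k, j] depends only on (nu_k, rho_k, y_j): changing other
        coordinates leaves the entry untouched."""
        rho = np.array([0.3, 0.6, 0.1])
        pot = Potential(u=np.zeros(3), rho=rho, activation=Activation.SIGMOID)
        y = np.array([1.0, 0.0])
        G1 = step_gradient(np.array([1, 0, 0]), pot, y)
        G2 = step_gradient(np.array([1, 1, 1]), pot, y)  # other neurons changed
        np.testing.assert_allclose(G1[0], G2[0])

    @pytest.mark.parametrize("activation", list(Activation))
    def test_matches_finite_difference_gradient(self, activation, rng):
        params = random_params(4, 3, activation, rng)
        sched = lambda t: one_hot(t % 3, 3)
        train = sample_trajectory(params, one_hot(0, 4), sched, 5, rng)
        G = trajectory_gradient(params, train)
        G_fd = finite_difference_theta_grad(params, train)
        np.testing.assert_allclose(G, G_fd, rtol=1e-4, atol=1e-6)


class TestEpisodicUpdates:
    def test_zero_reward_leaves_theta_fixed(self, rng):
        params = random_params(3, 2, Activation.SOFTMAX_WTA, rng)
        train = sample_trajectory(params, one_hot(0, 3), lambda t: one_hot(0, 2), 4, rng)
        out = online_update(params, train, 0.0, LearnConfig())
        np.testing.assert_array_equal(out.Theta, params.Theta)

    def test_single_context_column_locality(self, rng):
        params = random_params(3, 4, Activation.SOFTMAX_WTA, rng)
        # only context neuron 2 ever fires
        train = sample_trajectory(params, one_hot(0, 3), lambda t: one_hot(2, 4), 1, rng)
        out = online_update(params, train, 1.0, LearnConfig(eta=0.5))
        delta = out.Theta - params.Theta
        untouched = [0, 1, 3]
        np.testing.assert_allclose(delta[:, untouched], 0.0)
        assert np.any(delta[:, 2] != 0)

    def test_w_and_theta0_untouched(self, rng):
        params = random_params(3, 2, Activation.SOFTMAX_WTA, rng)
        train = sample_trajectory(params, one_hot(0, 3), lambda t: one_hot(0, 2), 4, rng)
        out = online_update(params, train, 1.0, LearnConfig())
        np.testing.assert_array_equal(out.W, params.W)
        np.testing.assert_array_equal(out.theta0, params.theta0)

    def test_offline_all_zero_rewards_noop(self, rng):
        params = random_params(3, 2, Activation.SOFTMAX_WTA, rng)

        def sampler(p, r):
            return sample_trajectory(p, one_hot(0, 3), lambda t: one_hot(0, 2), 3, r)

        out = offline_update(
            params, sampler, lambda tr: 0.0, LearnConfig(eta=0.5, L=5, mode="offline"), rng
        )
        np.testing.assert_array_equal(out.Theta, params.Theta)

    def test_training_without_reward_never_drifts(self, rng):
        params = random_params(3, 4, Activation.SOFTMAX_WTA, rng)
        out, _ = train_episodic(
            params,
            lambda r: one_hot(0, 3),
            lambda t: one_hot(t, 4),
            4,
            lambda tr: 0.0,
            LearnConfig(eta=0.5),
            50,
            rng,
        )
        np.testing.assert_array_equal(out.Theta, params.Theta)


class TestEligibilityTrace:
    def test_memoryless_when_decay_zero(self):
        cfg = LearnConfig(trace_decay=0.0)
        tr = EligibilityTrace(e=np.full((2, 2), 7.0))
        G = np.arange(4.0).reshape(2, 2)
        out = trace_step(tr, G, cfg)
        np.testing.assert_allclose(out.e, G)

    def test_geometric_decay_without_input(self):
        cfg = LearnConfig(trace_decay=0.5)
        tr = EligibilityTrace(e=np.ones((2, 1)))
        for _ in range(5):
            tr = trace_step(tr, np.zeros((2, 1)), cfg)
        np.testing.assert_allclose(tr.e, 0.5**5)

    def test_constant_input_geometric_series_closed_form(self):
        lam = 0.9
        cfg = LearnConfig(trace_decay=lam)
        G = np.array([[2.0, -1.0]])
        tr = EligibilityTrace.zeros(1, 2)
        n = 12
        for _ in range(n):
            tr = trace_step(tr, G, cfg)
        np.testing.assert_allclose(tr.e, G * (1 - lam**n) / (1 - lam), rtol=1e-12)

    def test_zero_reward_never_updates(self):
        params = NetworkParams(
            W=np.zeros((2, 2)), Theta=np.zeros((2, 1)), theta0=np.zeros(2)
        )
        tr = EligibilityTrace(e=np.ones((2, 1)))
        out = infinite_horizon_update(params, tr, 0.0, LearnConfig())
        np.testing.assert_array_equal(out.Theta, params.Theta)

    def test_end_reward_equals_discounted_episodic_gradient(self, rng):
        """Reward only at the episode end: applying the trace update once
        must equal eta * r * sum_t lambda^(T-t) G_t computed explicitly."""
        lam = 0.8
        cfg = LearnConfig(eta=0.3, trace_decay=lam, gamma=0.9)
        params = random_params(3, 2, Activation.SIGMOID, rng)
        sched = lambda t: one_hot(t % 2, 2)
        train = sample_trajectory(params, one_hot(0, 3), sched, 6, rng)
        # route 1: trace dynamics
        tr = EligibilityTrace.zeros(3, 2)
        v_prev = train.v0
        Gs = []
        for t in range(train.T):
            pot = membrane_potential(v_prev, train.contexts[t], params)
            G = step_gradient(train.states[t], pot, train.contexts[t])
            Gs.append(G)
            tr = trace_step(tr, G, cfg)
            v_prev = train.states[t]
        out = infinite_horizon_update(params, tr, 1.0, cfg)
        # route 2: explicit discounted sum oracle
        expected = sum(lam ** (train.T - 1 - t) * G for t, G in enumerate(Gs))
        np.testing.assert_allclose(
            out.Theta - params.Theta, cfg.eta * expected, atol=1e-10
        )


class TestFastTrainers:
    def test_finite_offline_matches_generic_gradients(self, toy_track):
        """One vectorised offline update equals the generic per-episode
        rule applied to the identically sampled batch."""
        from spikeplan import build_track_weights, track_context_schedule

        W = build_track_weights(toy_track)
        base = NetworkParams(
            W=W, Theta=np.zeros((9, 4)), theta0=np.zeros(9)
        )
        cfg = LearnConfig(eta=2.0, L=300, mode="offline")
        T = toy_track.T

        def reward_idx(traj):
            return (
                (traj[:, 2] == toy_track.passage_mid)
                & (traj[:, 4] == toy_track.passage_end)
            ).astype(float)

        seed = 77
        fast, _ = train_finite_offline(
            base, T, reward_idx, cfg, 1, np.random.default_rng(seed)
        )

        # replicate the batch with the same generator calls, then apply
        # the generic (per-episode) gradient machinery
        rng = np.random.default_rng(seed)
        P0 = softmax(W, axis=0)
        cum0 = np.cumsum(P0, axis=0)
        traj = np.empty((cfg.L, T + 1), dtype=np.int64)
        traj[:, 0] = rng.integers(9, size=cfg.L)
        for t in range(T):
            u = rng.random(cfg.L)
            traj[:, t + 1] = (cum0[:, traj[:, t]] < u[None, :]).sum(axis=0)
        r = reward_idx(traj)
        sched = track_context_schedule(toy_track)
        total = np.zeros((9, 4))
        for seq, rew in zip(traj, r):
            if rew == 0:
                continue
            from spikeplan import SpikeTrain

            train = SpikeTrain(
                states=np.stack([one_hot(s, 9) for s in seq[1:]]),
                contexts=np.stack([sched(t) for t in range(T)]),
                v0=one_hot(seq[0], 9),
            )
            total += rew * trajectory_gradient(base, train)
        expected = base.Theta + (cfg.eta / cfg.L) * total
        np.testing.assert_allclose(fast.Theta, expected, atol=1e-10)

    def test_train_maze_matches_generic_ops_single_episode(self):
        """The optimised maze loop reproduces the generic step-by-step
        trace rule bit for bit on one episode."""
        task = GridMazeTask(
            rows=4,
            cols=4,
            obstacles=frozenset(),
            start=(0, 0),
            target=(3, 3),
            T_max=40,
            gamma=0.9,
        )
        params = maze_params(task)
        cfg = LearnConfig(eta=0.7, L=1, mode="online", gamma=0.9)
        seed = 5
        fast, _ = train_maze(params, task, cfg, 1, np.random.default_rng(seed))

        rng = np.random.default_rng(seed)
        tr = EligibilityTrace.zeros(task.K, 1)
        cur = params
        v_prev = one_hot(task.cell_index(task.start), task.K)
        y = np.ones(1, dtype=np.int8)
        from spikeplan import sample_spikes

        for _ in range(task.T_max):
            pot = membrane_potential(v_prev, y, cur)
            v = sample_spikes(pot, cur.activation, rng)
            G = step_gradient(v, pot, y)
            tr = trace_step(tr, G, cfg)
            v_prev = v
            state = int(np.argmax(v))
            if state == task.cell_index(task.target):
                cur = infinite_horizon_update(cur, tr, task.r_goal, cfg)
                break
        np.testing.assert_allclose(fast.Theta, cur.Theta, atol=1e-12)


def test_learn_config_contracts():
    with pytest.raises(ValueError):
        LearnConfig(eta=-0.1)
    with pytest.raises(ValueError):
        LearnConfig(mode="online", L=5)
    with pytest.raises(ValueError):
        LearnConfig(gamma=1.5)
    cfg = LearnConfig(gamma=0.97)
    assert cfg.decay == 0.97  # trace decay defaults to the discount
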