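"""Unit and property tests for the stochastic network dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeplan import (
    Activation,
    NetworkParams,
    SpikeTrain,
    log_trajectory_prob,
    membrane_potential,
    one_hot,
    read_spike_train,
    sample_spikes,
    sample_trajectory,
    write_spike_train,
)

from conftest import random_params


def params_with_drive(u, activation):
    """Parameters whose potential equals ``u`` when neuron 0 fired last."""
    K = len(u)
    W = np.zeros((K, K))
    W[:, 0] = u
    return NetworkParams(
        W=W, Theta=np.zeros((K, 1)), theta0=np.zeros(K), activation=activation
    )


class TestMembranePotential:
    def test_zero_weights_softmax_is_uniform(self):
        p = params_with_drive([0.0, 0.0, 0.0, 0.0], Activation.SOFTMAX_WTA)
        pot = membrane_potential(one_hot(0, 4), np.zeros(1), p)
        np.testing.assert_allclose(pot.rho, 0.25)

    def test_zero_potential_sigmoid_is_half(self):
        p = params_with_drive([0.0, 0.0, 0.0], Activation.SIGMOID)
        pot = membrane_potential(one_hot(0, 3), np.zeros(1), p)
        np.testing.assert_allclose(pot.rho, 0.5)

    def test_softmax_against_logsumexp_oracle(self):
        # independent log-sum-exp evaluation, plain Python floats
        u = [1.0, 2.0, 3.0]
        lse = math.log(sum(math.exp(x) for x in u))
        expected = [math.exp(x - lse) for x in u]
        p = params_with_drive(u, Activation.SOFTMAX_WTA)
        pot = membrane_potential(one_hot(0, 3), np.zeros(1), p)
        np.testing.assert_allclose(pot.rho, expected, rtol=1e-12)

    def test_large_potentials_do_not_overflow(self):
        p = params_with_drive([900.0, 901.0, 899.0], Activation.SOFTMAX_WTA)
        pot = membrane_potential(one_hot(0, 3), np.zeros(1), p)
        assert np.all(np.isfinite(pot.rho))
        np.testing.assert_allclose(pot.rho.sum(), 1.0)

    def test_dimension_mismatch_raises(self):
        p = params_with_drive([0.0, 0.0], Activation.SOFTMAX_WTA)
        with pytest.raises(ValueError):
            membrane_potential(one_hot(0, 3), np.zeros(1), p)
        with pytest.raises(ValueError):
            membrane_potential(one_hot(0, 2), np.zeros(2), p)

    @given(
        u=st.lists(st.floats(-30, 30), min_size=2, max_size=6),
        c=st.floats(-50, 50),
    )
    @settings(deadline=None, max_examples=50)
    def test_softmax_shift_invariance(self, u, c):
        p1 = params_with_drive(u, Activation.SOFTMAX_WTA)
        p2 = params_with_drive([x + c for x in u], Activation.SOFTMAX_WTA)
        v = one_hot(0, len(u))
        r1 = membrane_potential(v, np.zeros(1), p1).rho
        r2 = membrane_potential(v, np.zeros(1), p2).rho
        np.testing.assert_allclose(r1, r2, atol=1e-10)


class TestSampleSpikes:
    def test_degenerate_categorical(self, rng):
        p = params_with_drive([1e3, 0.0, 0.0], Activation.SOFTMAX_WTA)
        pot = membrane_potential(one_hot(0, 3), np.zeros(1), p)
        for _ in range(20):
            v = sample_spikes(pot, Activation.SOFTMAX_WTA, rng)
            assert v.tolist() == [1, 0, 0]

    def test_sigmoid_zero_rates_silent(self, rng):
        p = params_with_drive([-1e3] * 4, Activation.SIGMOID)
        pot = membrane_potential(one_hot(0, 4), np.zeros(1), p)
        v = sample_spikes(pot, Activation.SIGMOID, rng)
        assert v.sum() == 0

    def test_wta_frequencies_match_rho(self, rng):
        """1e5 categorical draws agree with (0.2, 0.3, 0.5) within 3 sigma."""
        rho = np.array([0.2, 0.3, 0.5])
        u = np.log(rho)
        p = params_with_drive(u, Activation.SOFTMAX_WTA)
        pot = membrane_potential(one_hot(0, 3), np.zeros(1), p)
        n = 100_000
        counts = np.zeros(3)
        for _ in range(n):
            counts += sample_spikes(pot, Activation.SOFTMAX_WTA, rng)
        for k in range(3):
            sigma = math.sqrt(n * rho[k] * (1 - rho[k]))
            assert abs(counts[k] - n * rho[k]) < 3 * sigma


class TestSampleTrajectory:
    def test_absorbing_dynamics(self, rng):
        W = np.full((2, 2), -50.0)
        np.fill_diagonal(W, 50.0)
        p = NetworkParams(W=W, Theta=np.zeros((2, 1)), theta0=np.zeros(2))
        train = sample_trajectory(p, one_hot(0, 2), lambda t: np.zeros(1), 8, rng)
        assert np.all(train.state_indices() == 0)
        # probability-1 path has log-probability ~ 0
        assert log_trajectory_prob(train, p) == pytest.approx(0.0, abs=1e-20)

    def test_seed_determinism_bit_for_bit(self):
        p = random_params(5, 3, Activation.SOFTMAX_WTA, np.random.default_rng(7))
        sched = lambda t: one_hot(t % 3, 3)
        t1 = sample_trajectory(p, one_hot(2, 5), sched, 20, np.random.default_rng(99))
        t2 = sample_trajectory(p, one_hot(2, 5), sched, 20, np.random.default_rng(99))
        assert np.array_equal(t1.states, t2.states)
        assert np.array_equal(t1.contexts, t2.contexts)

    def test_sigmoid_rows_need_not_be_one_hot(self, rng):
        p = random_params(4, 2, Activation.SIGMOID, rng)
        train = sample_trajectory(p, one_hot(0, 4), lambda t: one_hot(0, 2), 10, rng)
        counts = train.states.sum(axis=1)
        assert counts.min() >= 0 and counts.max() <= 4


class TestLogTrajectoryProb:
    def test_uniform_dynamics_log_prob(self, rng):
        K, T = 4, 5
        p = NetworkParams(W=np.zeros((K, K)), Theta=np.zeros((K, 1)), theta0=np.zeros(K))
        train = sample_trajectory(p, one_hot(1, K), lambda t: np.zeros(1), T, rng)
        assert log_trajectory_prob(train, p) == pytest.approx(-T * math.log(K))

    @pytest.mark.parametrize("activation", list(Activation))
    def test_enumeration_sums_to_one_k3_t2(self, activation):
        """Exhaustive normalisation check on a random K=3, T=2 instance."""
        p = random_params(3, 2, activation, np.random.default_rng(5))
        sched = lambda t: one_hot(t, 2)
        v0 = one_hot(0, 3)
        if activation is Activation.SOFTMAX_WTA:
            rows = [one_hot(k, 3) for k in range(3)]
        else:
            rows = [np.array(b, dtype=np.int8) for b in np.ndindex(2, 2, 2)]
        total = 0.0
        for s1 in rows:
            for s2 in rows:
                train = SpikeTrain(
                    states=np.stack([s1, s2]),
                    contexts=np.stack([sched(0), sched(1)]),
                    v0=v0,
                )
                total += math.exp(log_trajectory_prob(train, p))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monte_carlo_visits_match_enumeration(self, rng):
        """State-visit frequencies over 1e4 WTA trajectories agree with
        the enumerated marginals within 4 sigma."""
        K, T = 3, 3
        p = random_params(K, 1, Activation.SOFTMAX_WTA, np.random.default_rng(11))
        sched = lambda t: np.ones(1, dtype=np.int8)
        v0 = one_hot(0, K)
        # enumerate marginal occupancy of the final step
        probs = {}
        for seq in np.ndindex(*([K] * T)):
            states = np.stack([one_hot(k, K) for k in seq])
            train = SpikeTrain(
                states=states, contexts=np.ones((T, 1), np.int8), v0=v0
            )
            probs[seq] = math.exp(log_trajectory_prob(train, p))
        marg_T = np.zeros(K)
        for seq, pr in probs.items():
            marg_T[seq[-1]] += pr
        n = 10_000
        counts = np.zeros(K)
        for _ in range(n):
            train = sample_trajectory(p, v0, sched, T, rng)
            counts[train.state_indices()[-1]] += 1
        for k in range(K):
            sigma = math.sqrt(n * marg_T[k] * (1 - marg_T[k]))
            assert abs(counts[k] - n * marg_T[k]) < 4 * max(sigma, 1.0)


def test_spike_train_csv_round_trip(tmp_path, rng):
    p = random_params(6, 4, Activation.SIGMOID, rng)
    train = sample_trajectory(p, one_hot(3, 6), lambda t: one_hot(t % 4, 4), 15, rng)
    path = tmp_path / "train.csv"
    write_spike_train(path, train, activation=p.activation, seed=42)
    back, meta = read_spike_train(path)
    assert np.array_equal(back.states, train.states)
    assert np.array_equal(back.contexts, train.contexts)
    assert np.array_equal(back.v0, train.v0)
    assert meta["K"] == 6 and meta["N"] == 4 and meta["seed"] == 42
    assert meta["activation"] == "sigmoid"
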