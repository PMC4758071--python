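"""Reward-modulated Hebbian plasticity of the context synapses Theta.

Learning treats planning as probabilistic inference: the network should
sample state trajectories from the posterior conditioned on a binary
reward event.  Ascending the likelihood of reward with respect to the
context weights yields, for exponential (softmax-WTA) and sigmoid
activations alike, the three-factor Hebbian rule

    d theta_kj  ~  eta * r * sum_t (nu_{t,k} - rho_{t,k}) * y_{t,j}

i.e. reward times the postsynaptic spike/rate discrepancy times the
presynaptic context activity.  For an arbitrary differentiable
activation the postsynaptic factor generalises to the derivative of the
per-step log-likelihood with respect to the membrane potential; that
hook is exposed via ``postsynaptic_factor``.

Finite-horizon episodes apply the summed update once per episode,
modulated by the terminal return (online, L = 1) or averaged over a
batch of L sampled episodes (offline).  Infinite-horizon tasks replace
the explicit sum by a per-synapse eligibility trace

    e_t = lambda * e_{t-1} + (nu_t - rho_t) y_t^T

decayed by the discount factor, with weight changes applied only at the
time steps where reward arrives.  Only Theta is learned; the recurrent
transition weights W are assumed known (or pre-learned, see
:mod:`spikeplan.transition_cd`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_softmax, softmax

from .network import (
    Activation,
    ContextSchedule,
    NetworkParams,
    Potential,
    SpikeTrain,
    membrane_potential,
    one_hot,
    sample_initial_state,
    sample_trajectory,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearnConfig:
    """Hyper-parameters of the plasticity rules.

    eta          learning rate.
    L            episodes per offline batch; online mode requires L = 1.
    mode         'online' (update after every episode) or 'offline'.
    gamma        discount factor for infinite-horizon tasks.
    trace_decay  eligibility decay per step; defaults to gamma, matching
                 the geometric prior over trajectory lengths that the
                 discount induces.
    """

    eta: float = 0.2
    L: int = 1
    mode: str = "online"
    gamma: float = 0.98
    trace_decay: float | None = None

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.mode not in ("online", "offline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "online" and self.L != 1:
            raise ValueError("online mode uses a single sample (L = 1)")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.trace_decay is not None and not 0 <= self.trace_decay <= 1:
            raise ValueError("trace_decay must lie in [0, 1]")

    @property
    def decay(self) -> float:
        return self.gamma if self.trace_decay is None else self.trace_decay


@dataclass
class EligibilityTrace:
    """K x N per-synapse accumulator; reset to zero at episode start."""

    e: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, K: int, N: int) -> "EligibilityTrace":
        return cls(e=np.zeros((K, N)), t=0)


PostsynapticFactor = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
"""(nu_t, u_t, rho_t) -> length-K vector d/du log p(nu | u)."""


def hebbian_factor(nu: np.ndarray, u: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Spike/rate discrepancy nu - rho: the exponential/sigmoid case."""
    return np.asarray(nu, float) - np.asarray(rho, float)


def step_gradient(
    nu_t: np.ndarray,
    pot: Potential,
    y_t: np.ndarray,
    activation: Activation | str | None = None,
    postsynaptic_factor: PostsynapticFactor = hebbian_factor,
) -> np.ndarray:
    """Per-step contribution G_t to the log-likelihood gradient wrt Theta.

    G_t[k, j] = factor_k * y_{t,j}; with the default Hebbian factor this
    is (nu_{t,k} - rho_{t,k}) * y_{t,j} for both WTA and sigmoid units.
    """
    factor = postsynaptic_factor(np.asarray(nu_t, float), pot.u, pot.rho)
    return np.outer(factor, np.asarray(y_t, float))


def trajectory_gradient(
    params: NetworkParams,
    train: SpikeTrain,
    postsynaptic_factor: PostsynapticFactor = hebbian_factor,
) -> np.ndarray:
    """sum_t G_t for a whole episode, with rho evaluated under ``params``."""
    G = np.zeros((params.K, params.N))
    v_prev = train.v0
    for t in range(train.T):
        pot = membrane_potential(v_prev, train.contexts[t], params)
        G += step_gradient(train.states[t], pot, train.contexts[t])
        v_prev = train.states[t]
    return G


def online_update(
    params: NetworkParams, train: SpikeTrain, reward: float, cfg: LearnConfig
) -> NetworkParams:
    """Single-episode update: Theta <- Theta + eta * r * sum_t G_t.

    W and the initial-state bias are left untouched; unrewarded episodes
    (r = 0) change nothing.
    """
    if reward == 0:
        return params
    G = trajectory_gradient(params, train)
    return params.with_theta(params.Theta + cfg.eta * reward * G)


def offline_update(
    params: NetworkParams,
    sampler: Callable[[NetworkParams, np.random.Generator], SpikeTrain],
    reward_fn: Callable[[SpikeTrain], float],
    cfg: LearnConfig,
    rng: np.random.Generator,
) -> NetworkParams:
    """Batch update from L sampled episodes.

    Theta <- Theta + (eta / L) * sum_l r^(l) * sum_t G_t^(l), where each
    episode is drawn by ``sampler`` (input-free random walk for the
    finite track, or the current model) and rho inside G is always
    evaluated under the *current* parameters.  An all-zero-reward batch
    is a logged no-op.
    """
    total = np.zeros_like(params.Theta)
    any_reward = False
    for _ in range(cfg.L):
        train = sampler(params, rng)
        r = reward_fn(train)
        if r != 0:
            any_reward = True
            total += r * trajectory_gradient(params, train)
    if not any_reward:
        logger.debug("offline batch had no rewarded episodes; no-op update")
        return params
    return params.with_theta(params.Theta + (cfg.eta / cfg.L) * total)


def trace_step(
    trace: EligibilityTrace, G_t: np.ndarray, cfg: LearnConfig
) -> EligibilityTrace:
    """e_t = decay * e_{t-1} + G_t."""
    if G_t.shape != trace.e.shape:
        raise ValueError("gradient and trace shapes disagree")
    return EligibilityTrace(e=cfg.decay * trace.e + G_t, t=trace.t + 1)


def infinite_horizon_update(
    params: NetworkParams,
    trace: EligibilityTrace,
    r_t: float,
    cfg: LearnConfig,
) -> NetworkParams:
    """Apply Theta <- Theta + eta * r_t * e_t at reward steps only.

    Derived for sigmoid dynamics but the Hebbian trace contents are
    identical under WTA sampling, so the rule is activation-agnostic
    here.  The raw (undiscounted) reward is used; the discount is folded
    into the trace decay.
    """
    if r_t == 0:
        return params
    return params.with_theta(params.Theta + cfg.eta * r_t * trace.e)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

@dataclass
class LearningCurve:
    """Per-update log of a training run (writable as CSV)."""

    iterations: list[int] = field(default_factory=list)
    mean_reward: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)
    seed: int | None = None

    def append(self, iteration: int, mean_reward: float, kl: float = np.nan) -> None:
        self.iterations.append(iteration)
        self.mean_reward.append(mean_reward)
        self.kl.append(kl)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iterations,
                "mean_reward": self.mean_reward,
                "kl_estimate": self.kl,
                "seed": self.seed,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def train_episodic(
    params: NetworkParams,
    v0_sampler: Callable[[np.random.Generator], np.ndarray],
    context_schedule: ContextSchedule,
    T: int,
    reward_fn: Callable[[SpikeTrain], float],
    cfg: LearnConfig,
    n_iterations: int,
    rng: np.random.Generator,
    *,
    kl_fn: Callable[[NetworkParams], float] | None = None,
    kl_every: int = 100,
    log_every: int = 100,
) -> tuple[NetworkParams, LearningCurve]:
    """Finite-horizon training for ``n_iterations`` episodes or batches.

    Online mode samples one episode from the current model and applies
    :func:`online_update`.  Offline mode draws L input-free random walks
    (context clamped to zero — "samples from a fixed distribution") per
    batch and applies :func:`offline_update`.
    """
    curve = LearningCurve()
    reward_window: list[float] = []

    zero_context = np.zeros(params.N, dtype=np.int8)

    def prior_sampler(p: NetworkParams, r: np.random.Generator) -> SpikeTrain:
        # input-free random walk; context rows recorded as the schedule
        # actually used at evaluation time so that G_t picks up y_t
        v0 = v0_sampler(r)
        walk_params = p.with_theta(np.zeros_like(p.Theta))
        train = sample_trajectory(walk_params, v0, lambda t: zero_context, T, r)
        train.contexts = np.stack(
            [np.asarray(context_schedule(t), np.int8) for t in range(T)]
        )
        return train

    for it in range(1, n_iterations + 1):
        if cfg.mode == "online":
            v0 = v0_sampler(rng)
            train = sample_trajectory(params, v0, context_schedule, T, rng)
            r = reward_fn(train)
            params = online_update(params, train, r, cfg)
            reward_window.append(r)
        else:
            rewards: list[float] = []

            def reward_logged(train: SpikeTrain) -> float:
                r = reward_fn(train)
                rewards.append(r)
                return r

            params = offline_update(params, prior_sampler, reward_logged, cfg, rng)
            reward_window.extend(rewards)
        if it % log_every == 0 or it == n_iterations:
            kl = np.nan
            if kl_fn is not None and (it % kl_every == 0 or it == n_iterations):
                kl = kl_fn(params)
            curve.append(it, float(np.mean(reward_window)), kl)
            reward_window = []
            logger.info(
                "iteration %d mean reward %.3f%s",
                it,
                curve.mean_reward[-1],
                "" if np.isnan(kl) else f" KL {kl:.4f}",
            )
    return params, curve


def train_finite_offline(
    params: NetworkParams,
    T: int,
    reward_idx_fn: Callable[[np.ndarray], np.ndarray],
    cfg: LearnConfig,
    n_updates: int,
    rng: np.random.Generator,
    *,
    eta_schedule: Callable[[int], float] | None = None,
    kl_fn: Callable[[NetworkParams], float] | None = None,
    kl_every: int = 50,
) -> tuple[NetworkParams, LearningCurve]:
    """Vectorised offline learning for finite-horizon WTA tasks with a
    one-context-neuron-per-step schedule.

    Mathematically identical to :func:`offline_update` with the
    input-free uniform-start random-walk sampler (the test suite checks
    the equivalence), but samples the whole batch of L random walks at
    once — the sampling distribution is fixed, so the walks never
    depend on the evolving Theta.  ``reward_idx_fn`` maps an
    L x (T+1) state-index array (column 0 = v_0) to L rewards.
    ``eta_schedule`` optionally replaces the constant learning rate by
    eta(update_index), e.g. a Robbins-Monro decay for tight posterior
    matching.
    """
    K = params.K
    if params.N != T:
        raise ValueError("expected one context neuron per time step (N = T)")
    theta = params.Theta.copy()
    P0 = softmax(params.W, axis=0)
    cum0 = np.cumsum(P0, axis=0)
    curve = LearningCurve()
    for it in range(1, n_updates + 1):
        eta = cfg.eta if eta_schedule is None else eta_schedule(it - 1)
        traj = np.empty((cfg.L, T + 1), dtype=np.int64)
        traj[:, 0] = rng.integers(K, size=cfg.L)
        for t in range(T):
            u = rng.random(cfg.L)
            traj[:, t + 1] = (cum0[:, traj[:, t]] < u[None, :]).sum(axis=0)
        r = np.asarray(reward_idx_fn(traj), dtype=float)
        hit = r > 0
        if np.any(hit):
            w = r[hit]
            sub = traj[hit]
            for t in range(T):
                P = softmax(params.W + theta[:, t : t + 1], axis=0)
                grad = np.zeros(K)
                np.add.at(grad, sub[:, t + 1], w)
                grad -= P[:, sub[:, t]] @ w
                theta[:, t] += (eta / cfg.L) * grad
        if kl_fn is not None and (it % kl_every == 0 or it == n_updates):
            cur = params.with_theta(theta)
            curve.append(it, float(np.mean(r)), kl_fn(cur))
    return params.with_theta(theta), curve


def train_maze(
    params: NetworkParams,
    task,
    cfg: LearnConfig,
    n_trials: int,
    rng: np.random.Generator,
    *,
    log_every: int = 500,
) -> tuple[NetworkParams, LearningCurve]:
    """Infinite-horizon eligibility-trace training on a grid-maze task.

    Episodes are drawn from the current model (self-normalised EM); the
    per-episode inner loop is a vectorised restatement of
    :func:`trace_step` + :func:`infinite_horizon_update` with a single
    always-on context neuron: within an episode Theta is constant, so
    the one-step transition matrix softmax_k(W[k, i] + theta_k) can be
    computed once per episode and each step reduces to an inverse-CDF
    draw plus a rank-one trace update.  Equivalence with the generic
    operations is covered by the test suite.

    Offline mode accumulates the reward-triggered updates of a batch of
    L episodes and applies their average; online mode (L = 1) applies
    them at the end of every episode.
    """
    from .tasks import GridMazeTask  # local import to avoid a cycle

    assert isinstance(task, GridMazeTask)
    K = params.K
    if params.N != 1:
        raise ValueError("train_maze expects a single always-on context neuron")
    target = task.cell_index(task.target)
    start = task.cell_index(task.start)
    theta = params.Theta.copy()  # (K, 1)
    curve = LearningCurve()
    batch_delta = np.zeros_like(theta)
    batch_count = 0
    reward_window: list[float] = []

    for trial in range(1, n_trials + 1):
        logits = params.W + theta  # column i = log-odds of next state
        P = softmax(logits, axis=0)
        cum = np.cumsum(P, axis=0)
        e = np.zeros(K)
        state = start
        disc_return = 0.0
        for t in range(task.T_max):
            col = cum[:, state]
            nxt = int(np.searchsorted(col, rng.random() * col[-1], side="right"))
            nxt = min(nxt, K - 1)
            e = cfg.decay * e + (one_hot(nxt, K) - P[:, state])
            state = nxt
            if state == target:
                disc_return = task.r_goal * cfg.gamma**t
                batch_delta[:, 0] += cfg.eta * task.r_goal * e
                break
        batch_count += 1
        reward_window.append(disc_return)
        if batch_count == cfg.L:
            theta = theta + batch_delta / cfg.L
            batch_delta = np.zeros_like(theta)
            batch_count = 0
        if trial % log_every == 0 or trial == n_trials:
            curve.append(trial, float(np.mean(reward_window)))
            reward_window = []
            logger.info(
                "trial %d mean discounted return %.4f", trial, curve.mean_reward[-1]
            )
    return params.with_theta(theta), curve
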