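"""Ground-truth machinery: exact posteriors, KL, MC evaluation, success rates.

Planning as inference has an exact answer on small instances: the
reward-conditioned trajectory posterior

    p(v_{0:T} | r = 1)  ~  p(v_0) prod_t p(v_t | v_{t-1}) * p(r=1 | v_{0:T})

can be enumerated outright when K^T is modest, which provides the
oracle against which the trained network's sampled distribution is
measured (Kullback-Leibler divergence).  The maze is too large to
enumerate, so the baseline there is first-visit Monte-Carlo policy
evaluation of discounted returns, plus binomial success rates with
Wilson confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import log_softmax, logsumexp
from statsmodels.stats.proportion import proportion_confint

from .network import NetworkParams, SpikeTrain, log_trajectory_prob
from .tasks import GridMazeTask

#: refuse to enumerate more than this many trajectories
ENUMERATION_GUARD = 10**6


@dataclass(frozen=True)
class ExactPosterior:
    """Exhaustive reward-conditioned posterior over WTA trajectories.

    ``support`` is an M x (T+1) integer array of state-index sequences
    (column 0 = v_0); ``probs`` the posterior probability of each; and
    ``init_logp`` the length-K log initial distribution shared with any
    model the posterior is compared against.
    """

    support: np.ndarray
    probs: np.ndarray
    init_logp: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("posterior probabilities do not sum to 1")

    @property
    def K(self) -> int:
        return self.init_logp.size

    @property
    def T(self) -> int:
        return self.support.shape[1] - 1

    def marginals(self) -> np.ndarray:
        """(T+1) x K per-step state-occupancy marginals."""
        M = np.zeros((self.support.shape[1], self.K))
        for t in range(self.support.shape[1]):
            np.add.at(M[t], self.support[:, t], self.probs)
        return M


def enumerate_trajectories(K: int, T: int) -> np.ndarray:
    """All K^T state-index sequences of length T as a (K^T, T) array."""
    n = K**T
    idx = np.arange(n)
    out = np.empty((n, T), dtype=np.int64)
    for t in range(T - 1, -1, -1):
        out[:, t] = idx % K
        idx //= K
    return out


def enumerate_posterior(
    W: np.ndarray,
    reward_fn: Callable[[np.ndarray], float],
    K: int,
    T: int,
    *,
    init_state: int | None = None,
    init_logp: np.ndarray | None = None,
    condition_on_init: bool = False,
) -> ExactPosterior:
    """Brute-force reward-conditioned posterior for WTA dynamics.

    ``reward_fn`` maps a length-(T+1) state-index sequence (including
    v_0) to a non-negative reward likelihood.  The initial distribution
    is uniform unless ``init_state`` (point mass) or ``init_logp`` is
    given.  Refuses instances beyond the 10^6-trajectory guardrail and
    errors when every trajectory has zero reward (undefined posterior).

    With ``condition_on_init`` the reward conditioning is applied per
    start state: p(traj) = p(v_0) * p(v_{1:T} | v_0, r=1).  This is the
    posterior a network that always *starts from* v_0 can actually
    represent (its initial distribution is not a learnable parameter),
    and the form whose divergence from the trained model goes to zero.
    Every start state must then have positive reward mass.
    """
    if K**T > ENUMERATION_GUARD:
        raise ValueError(
            f"enumeration of K^T = {K}^{T} = {K**T} trajectories exceeds "
            f"the guardrail of {ENUMERATION_GUARD}"
        )
    if init_logp is None:
        init_logp = np.full(K, -np.log(K))
        if init_state is not None:
            init_logp = np.full(K, -np.inf)
            init_logp[init_state] = 0.0
    logP = log_softmax(np.asarray(W, dtype=float), axis=0)  # logP[k, i]

    v0s = (
        np.arange(K) if init_state is None else np.array([init_state])
    )
    tails = enumerate_trajectories(K, T)
    support = np.empty((v0s.size * tails.shape[0], T + 1), dtype=np.int64)
    support[:, 0] = np.repeat(v0s, tails.shape[0])
    support[:, 1:] = np.tile(tails, (v0s.size, 1))

    log_prior = init_logp[support[:, 0]].astype(float)
    for t in range(T):
        log_prior += logP[support[:, t + 1], support[:, t]]
    rewards = np.array([float(reward_fn(traj)) for traj in support])
    if not np.any(rewards > 0):
        raise ValueError("all trajectories have zero reward; posterior undefined")
    with np.errstate(divide="ignore"):
        log_w = log_prior + np.log(rewards)
    if condition_on_init:
        n_tail = tails.shape[0]
        probs = np.empty_like(log_w)
        for b, v0 in enumerate(v0s):
            blk = slice(b * n_tail, (b + 1) * n_tail)
            z = logsumexp(log_w[blk])
            if np.isneginf(z):
                raise ValueError(
                    f"start state {v0} has zero reward mass; conditional "
                    "posterior undefined"
                )
            # block log-weights include init_logp[v0]; subtracting the
            # block normaliser and re-adding init mass conditions per v0
            probs[blk] = np.exp(log_w[blk] - z + init_logp[v0])
        return ExactPosterior(support=support, probs=probs, init_logp=init_logp)
    log_Z = logsumexp(log_w)
    return ExactPosterior(
        support=support, probs=np.exp(log_w - log_Z), init_logp=init_logp
    )


def model_log_probs(
    posterior: ExactPosterior,
    params: NetworkParams,
    context_schedule: Callable[[int], np.ndarray],
) -> np.ndarray:
    """log q(traj) under the network for every trajectory in the support,
    sharing the posterior's initial distribution."""
    T = posterior.T
    # per-step conditional log-probability matrices under the model
    logQ = np.empty((T, params.K, params.K))
    for t in range(T):
        y = np.asarray(context_schedule(t), dtype=float)
        logQ[t] = log_softmax(params.W + (params.Theta @ y)[:, None], axis=0)
    logq = posterior.init_logp[posterior.support[:, 0]].astype(float)
    for t in range(T):
        logq += logQ[t][posterior.support[:, t + 1], posterior.support[:, t]]
    return logq


def kl_model_vs_posterior(
    params: NetworkParams,
    posterior: ExactPosterior,
    context_schedule: Callable[[int], np.ndarray],
) -> float:
    """KL(true posterior || model) in nats; +inf if the model assigns
    zero probability to a supported trajectory."""
    logq = model_log_probs(posterior, params, context_schedule)
    p = posterior.probs
    mask = p > 0
    if np.any(np.isneginf(logq[mask])):
        return np.inf
    return float(np.sum(p[mask] * (np.log(p[mask]) - logq[mask])))


# ---------------------------------------------------------------------------
# Monte-Carlo baselines
# ---------------------------------------------------------------------------

@dataclass
class ValueTable:
    """First-visit MC estimates of discounted return per maze cell."""

    values: np.ndarray
    counts: np.ndarray
    mean_return: float


def mc_policy_evaluation(
    task: GridMazeTask,
    policy: Callable[[np.random.Generator], tuple[list[int], bool]],
    n_episodes: int,
    rng: np.random.Generator,
) -> ValueTable:
    """First-visit Monte-Carlo policy evaluation on the maze.

    ``policy`` samples one episode: a list of visited state indices
    (excluding the start) and whether the target was reached.  Rewards
    are r_goal at the target only, discounted by gamma per step.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    K = task.K
    totals = np.zeros(K)
    counts = np.zeros(K)
    start = task.cell_index(task.start)
    returns = []
    for _ in range(n_episodes):
        path, reached = policy(rng)
        states = [start] + list(path)
        T = len(path)
        # terminal reward at the last step iff the target was reached
        rewards = np.zeros(T + 1)
        if reached:
            rewards[-1] = task.r_goal
        # discounted return-to-go at each visit
        G = 0.0
        rtg = np.zeros(T + 1)
        for t in range(T, -1, -1):
            G = rewards[t] + task.gamma * G
            rtg[t] = G
        returns.append(rtg[0])
        seen: set[int] = set()
        for t, s in enumerate(states):
            if s not in seen:
                seen.add(s)
                totals[s] += rtg[t]
                counts[s] += 1
    values = np.divide(totals, counts, out=np.zeros(K), where=counts > 0)
    return ValueTable(values=values, counts=counts, mean_return=float(np.mean(returns)))


@dataclass(frozen=True)
class SuccessRate:
    """Binomial success fraction with a 95% Wilson confidence interval."""

    rate: float
    low: float
    high: float
    n: int


def success_rate(
    sampler: Callable[[np.random.Generator], float],
    n_trials: int,
    rng: np.random.Generator,
) -> SuccessRate:
    """Fraction of trials with positive reward; ``sampler`` runs one
    trial and returns its reward."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    wins = sum(1 for _ in range(n_trials) if sampler(rng) > 0)
    low, high = proportion_confint(wins, n_trials, alpha=0.05, method="wilson")
    return SuccessRate(rate=wins / n_trials, low=float(low), high=float(high), n=n_trials)
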