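"""Stochastic two-layer recurrent network for planning by sampling.

A layer of K *state neurons* carries the agent's state; a layer of N
afferent *context neurons* injects goal and constraint information.  At
each discrete time step the membrane potential of state neuron k is

    u_{t,k} = sum_i W[k, i] * nu_{t-1, i} + sum_j Theta[k, j] * y_{t, j}

and spikes are drawn from an activation-dependent distribution:

* ``softmax_wta`` -- hard winner-take-all: exactly one neuron fires,
  drawn categorically from softmax(u).  One neuron maps to one discrete
  state, so the recurrent weights W encode a log state-transition model.
* ``sigmoid`` -- each neuron fires an independent Bernoulli with
  probability expit(u_k); several (or no) neurons may fire per step.

Time is discrete with a unit step; wall-clock durations are mapped to
step counts via ``MS_PER_STEP`` (default 20 ms per step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, log_softmax, softmax

#: Wall-clock milliseconds represented by one discrete network step.
MS_PER_STEP: float = 20.0


class Activation(str, Enum):
    """Spike-sampling contract of the state layer."""

    SOFTMAX_WTA = "softmax_wta"
    SIGMOID = "sigmoid"


@dataclass(frozen=True)
class NetworkParams:
    """Synaptic parameters of the planner network.

    Parameters
    ----------
    W
        K x K recurrent state->state weights; ``W[k, i]`` is the drive
        from presynaptic state neuron i onto k.  Under WTA dynamics with
        zero context, column i of W is the log transition distribution
        out of state i (up to a softmax constant).
    Theta
        K x N context->state weights; the only parameters adapted by the
        reward-modulated plasticity rules.
    theta0
        Length-K initial-state bias: the initial spike vector v_0 is
        drawn from softmax(theta0), so a strongly peaked theta0 pins the
        agent to a fixed start state and a zero theta0 gives the uniform
        initial distribution.
    activation
        Sampling contract, see :class:`Activation`.
    """

    W: np.ndarray
    Theta: np.ndarray
    theta0: np.ndarray
    activation: Activation = Activation.SOFTMAX_WTA

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        Theta = np.asarray(self.Theta, dtype=float)
        theta0 = np.asarray(self.theta0, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "Theta", Theta)
        object.__setattr__(self, "theta0", theta0)
        object.__setattr__(self, "activation", Activation(self.activation))
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square K x K, got {W.shape}")
        K = W.shape[0]
        if Theta.ndim != 2 or Theta.shape[0] != K:
            raise ValueError(
                f"Theta must be K x N with K={K}, got {Theta.shape}"
            )
        if theta0.shape != (K,):
            raise ValueError(f"theta0 must have shape ({K},), got {theta0.shape}")
        if K < 1 or Theta.shape[1] < 1:
            raise ValueError("need K >= 1 state and N >= 1 context neurons")
        for name, arr in (("W", W), ("Theta", Theta), ("theta0", theta0)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def K(self) -> int:
        return self.W.shape[0]

    @property
    def N(self) -> int:
        return self.Theta.shape[1]

    def with_theta(self, Theta: np.ndarray) -> "NetworkParams":
        """Copy of the parameters with the context weights replaced."""
        return replace(self, Theta=np.asarray(Theta, dtype=float))


@dataclass(frozen=True)
class Potential:
    """Membrane potentials and the induced firing probabilities."""

    u: np.ndarray
    rho: np.ndarray
    activation: Activation


@dataclass
class SpikeTrain:
    """A sampled trajectory of the network.

    ``states[t]`` is the state-layer spike vector v_{t+1} (t = 0 .. T-1)
    and ``contexts[t]`` the context pattern y_{t+1} that drove it; the
    initial state v_0 is stored separately.
    """

    states: np.ndarray  # (T, K) binary
    contexts: np.ndarray  # (T, N) binary
    v0: np.ndarray  # (K,) binary

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.contexts = np.asarray(self.contexts, dtype=np.int8)
        self.v0 = np.asarray(self.v0, dtype=np.int8)
        if self.states.ndim != 2 or self.contexts.ndim != 2:
            raise ValueError("states and contexts must be 2-D (T x width)")
        if self.states.shape[0] != self.contexts.shape[0]:
            raise ValueError("states and contexts disagree on T")
        if self.states.shape[0] < 1:
            raise ValueError("a spike train needs T >= 1 steps")
        if self.v0.shape != (self.states.shape[1],):
            raise ValueError("v0 width does not match the state layer")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def K(self) -> int:
        return self.states.shape[1]

    @property
    def N(self) -> int:
        return self.contexts.shape[1]

    def state_indices(self) -> np.ndarray:
        """Active-state index per step; requires one spike per step (WTA)."""
        if not np.all(self.states.sum(axis=1) == 1):
            raise ValueError("state rows are not one-hot; not a WTA train")
        return np.argmax(self.states, axis=1)


ContextSchedule = Callable[[int], np.ndarray]
"""Maps a 0-based step index t to the context spike vector y_{t+1}."""


def one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size, dtype=np.int8)
    v[index] = 1
    return v


def membrane_potential(
    v_prev: np.ndarray, y_t: np.ndarray, params: NetworkParams
) -> Potential:
    """Affine drive and firing probabilities for one network step.

    u = W @ v_prev + Theta @ y_t; rho = softmax(u) under WTA (computed
    with max-subtraction) or expit(u) under sigmoid dynamics.
    """
    v_prev = np.asarray(v_prev, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if v_prev.shape != (params.K,):
        raise ValueError(f"v_prev has shape {v_prev.shape}, expected ({params.K},)")
    if y_t.shape != (params.N,):
        raise ValueError(f"y_t has shape {y_t.shape}, expected ({params.N},)")
    u = params.W @ v_prev + params.Theta @ y_t
    if params.activation is Activation.SOFTMAX_WTA:
        rho = softmax(u)
    else:
        rho = expit(u)
    return Potential(u=u, rho=rho, activation=params.activation)


def sample_spikes(
    pot: Potential, activation: Activation, rng: np.random.Generator
) -> np.ndarray:
    """Draw one spike vector from the firing probabilities.

    WTA: a single categorical draw by inverse-CDF on rho.  Sigmoid:
    independent Bernoulli per neuron.  Reproducible given the generator
    state; no deterministic argmax is used anywhere.
    """
    activation = Activation(activation)
    rho = np.asarray(pot.rho, dtype=float)
    if activation is Activation.SOFTMAX_WTA:
        cdf = np.cumsum(rho)
        idx = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
        return one_hot(min(idx, rho.size - 1), rho.size)
    return (rng.random(rho.size) < rho).astype(np.int8)


def sample_trajectory(
    params: NetworkParams,
    v0: np.ndarray,
    context_schedule: ContextSchedule,
    T: int,
    rng: np.random.Generator,
) -> SpikeTrain:
    """Roll the network forward for T steps from initial state v0."""
    if T < 1:
        raise ValueError("T must be >= 1")
    v = np.asarray(v0, dtype=np.int8)
    states = np.zeros((T, params.K), dtype=np.int8)
    contexts = np.zeros((T, params.N), dtype=np.int8)
    for t in range(T):
        y = np.asarray(context_schedule(t), dtype=np.int8)
        pot = membrane_potential(v, y, params)
        v = sample_spikes(pot, params.activation, rng)
        states[t] = v
        contexts[t] = y
    return SpikeTrain(states=states, contexts=contexts, v0=np.asarray(v0, np.int8))


def sample_initial_state(params: NetworkParams, rng: np.random.Generator) -> np.ndarray:
    """Draw v_0 from softmax(theta0) (always a single active neuron)."""
    rho = softmax(params.theta0)
    cdf = np.cumsum(rho)
    idx = int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))
    return one_hot(min(idx, params.K - 1), params.K)


def step_log_prob(
    nu_t: np.ndarray, v_prev: np.ndarray, y_t: np.ndarray, params: NetworkParams
) -> float:
    """log p(v_t | v_{t-1}, y_t) for one step, computed stably."""
    u = params.W @ np.asarray(v_prev, float) + params.Theta @ np.asarray(y_t, float)
    nu = np.asarray(nu_t, dtype=float)
    if params.activation is Activation.SOFTMAX_WTA:
        if nu.sum() != 1:
            return -np.inf
        return float(log_softmax(u)[np.argmax(nu)])
    return float(np.sum(nu * log_expit(u) + (1.0 - nu) * log_expit(-u)))


def log_trajectory_prob(train: SpikeTrain, params: NetworkParams) -> float:
    """Exact log-probability sum_t log p(v_t | v_{t-1}, y_t) of a train.

    A zero-probability step yields ``-inf`` (flagged to the caller by the
    return value; no exception).
    """
    if train.K != params.K or train.N != params.N:
        raise ValueError("spike train dimensions do not match the parameters")
    total = 0.0
    v_prev = train.v0
    for t in range(train.T):
        total += step_log_prob(train.states[t], v_prev, train.contexts[t], params)
        v_prev = train.states[t]
    return total


# ---------------------------------------------------------------------------
# Spike-train CSV interchange
# ---------------------------------------------------------------------------

def write_spike_train(
    path: str | Path,
    train: SpikeTrain,
    *,
    activation: Activation | str,
    seed: int | None = None,
) -> None:
    """Write a spike train to ``path`` as CSV plus a JSON metadata sidecar.

    The CSV holds one row per spike: (t, layer, neuron_id, spike) with
    layer in {state, context} and t = 0 reserved for the initial state
    v_0; steps are 1-based in the file.  Zero entries are implied by the
    (T, K, N) stored in ``<path>.meta.json``, so the round trip is
    lossless.
    """
    path = Path(path)
    rows: list[tuple[int, str, int, int]] = []
    for k in np.flatnonzero(train.v0):
        rows.append((0, "state", int(k), 1))
    for t in range(train.T):
        for k in np.flatnonzero(train.states[t]):
            rows.append((t + 1, "state", int(k), 1))
        for j in np.flatnonzero(train.contexts[t]):
            rows.append((t + 1, "context", int(j), 1))
    pd.DataFrame(rows, columns=["t", "layer", "neuron_id", "spike"]).to_csv(
        path, index=False
    )
    meta = {
        "T": int(train.T),
        "K": int(train.K),
        "N": int(train.N),
        "activation": str(Activation(activation).value),
        "seed": seed,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_spike_train(path: str | Path) -> tuple[SpikeTrain, dict]:
    """Inverse of :func:`write_spike_train`; returns (train, metadata)."""
    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    T, K, N = meta["T"], meta["K"], meta["N"]
    df = pd.read_csv(path, comment="#")
    states = np.zeros((T, K), dtype=np.int8)
    contexts = np.zeros((T, N), dtype=np.int8)
    v0 = np.zeros(K, dtype=np.int8)
    for _, row in df.iterrows():
        t, layer, nid = int(row["t"]), row["layer"], int(row["neuron_id"])
        if t == 0:
            v0[nid] = 1
        elif layer == "state":
            states[t - 1, nid] = 1
        else:
            contexts[t - 1, nid] = 1
    return SpikeTrain(states=states, contexts=contexts, v0=v0), meta
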