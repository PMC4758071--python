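"""Hippocampal-sweep simulation: goal-directed transient place-cell firing.

A 10 x 10 sheet of place cells covering a 2 x 2 m arena is driven by 20
context neurons and a Gaussian recurrent kernel — no learning is
involved.  The first ten context neurons encode the animal's current
(resting) location through a transient pattern active only during an
initialisation window (200 ms by default); the remaining ten encode the
remembered home location and fire as a stationary Poisson process
throughout the event.  Context weights are an affine decreasing
function of the Euclidean distance between a cell's preferred position
and the respective anchor, so cells near the anchors receive the
largest drive.  The recurrent weights implement a Gaussian transition
kernel that forbids teleports: activity can only drift smoothly, so the
sampled trajectory sweeps from the start towards home instead of
jumping straight to the goal.

The state layer is a soft winner-take-all: sigmoid-style Bernoulli
units whose firing probabilities are divisively normalised to an
expected population rate (``n_active`` spikes per step), letting
several place cells fire simultaneously while keeping the population
decode well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax

from .network import MS_PER_STEP, SpikeTrain
from .population import PlaceCode, decode_trajectory, grid_code


@dataclass(frozen=True)
class SweepConfig:
    """Parameters of the sweep simulation (distances in metres)."""

    rows: int = 10
    cols: int = 10
    extent: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 2.0),
        (0.0, 2.0),
    )
    n_start_context: int = 10
    n_home_context: int = 10
    #: steps with the transient start group active: 200 ms at 20 ms/step
    init_window: int = int(round(200.0 / MS_PER_STEP))
    #: per-step firing probability of the stationary-Poisson home group
    poisson_rate: float = 0.5
    #: width of the Gaussian recurrent transition kernel
    sigma_trans: float = 0.25
    #: affine distance-to-weight map theta = a - b * distance; the slope
    #: is set so the summed home-context gain (~5 active neurons * b * d)
    #: stays below the quadratic recurrent penalty d^2/(2 sigma^2) beyond
    #: roughly one kernel width -- context pulls the bump but cannot
    #: teleport it
    weight_scale: float = 1.0
    weight_slope: float = 0.5
    #: expected number of simultaneously active place cells per step
    n_active: float = 3.0
    #: resting location at the arena centre (isotropic diffusion there
    #: makes the silenced-goal control clean); home towards a corner
    start: tuple[float, float] = (1.0, 1.0)
    home: tuple[float, float] = (1.7, 1.7)

    def __post_init__(self) -> None:
        if self.init_window < 1:
            raise ValueError("init_window must be >= 1")
        if not 0 < self.poisson_rate < 1:
            raise ValueError("poisson_rate must lie in (0, 1)")
        if self.sigma_trans <= 0:
            raise ValueError("sigma_trans must be positive")
        if self.n_active < 1:
            raise ValueError("n_active must be >= 1")

    @property
    def N(self) -> int:
        return self.n_start_context + self.n_home_context

    def place_code(self) -> PlaceCode:
        return grid_code(self.rows, self.cols, self.extent)


def distance_weights(
    code: PlaceCode, anchor: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Affine decreasing map of distance to synaptic weight.

    theta_k = a - b * ||p_k - anchor||_2, so the drive peaks at the cell
    containing the anchor.  (The distance-proportional magnitude with a
    decreasing sign is required for anchored drive; an increasing map
    would repel activity from the anchor.)
    """
    if b <= 0:
        raise ValueError("weight slope b must be positive")
    anchor = np.asarray(anchor, dtype=float)
    if np.any(anchor < code.lower) or np.any(anchor > code.upper):
        raise ValueError("anchor lies outside the arena")
    return a - b * np.linalg.norm(code.positions - anchor, axis=1)


def gaussian_transition_weights(code: PlaceCode, sigma: float) -> np.ndarray:
    """Recurrent kernel w_ki = -||p_k - p_i||^2 / (2 sigma^2).

    The softmax of a one-hot previous state then yields a discretised
    isotropic Gaussian centred on that cell, which is what keeps the
    sampled activity spatially contiguous.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    diff = code.positions[:, None, :] - code.positions[None, :, :]
    return -np.einsum("kid,kid->ki", diff, diff) / (2.0 * sigma**2)


def sweep_context_weights(cfg: SweepConfig, code: PlaceCode) -> np.ndarray:
    """K x 20 context weights: columns 0..9 anchored at the start
    location, columns 10..19 at the home location."""
    w_start = distance_weights(code, cfg.start, cfg.weight_scale, cfg.weight_slope)
    w_home = distance_weights(code, cfg.home, cfg.weight_scale, cfg.weight_slope)
    Theta = np.empty((code.K, cfg.N))
    Theta[:, : cfg.n_start_context] = w_start[:, None]
    Theta[:, cfg.n_start_context :] = w_home[:, None]
    return Theta


def sweep_context_schedule(
    cfg: SweepConfig, T: int, rng: np.random.Generator, *, home_active: bool = True
) -> np.ndarray:
    """T x 20 context raster: start group on for t < init_window, home
    group stationary Bernoulli(poisson_rate) throughout."""
    Y = np.zeros((T, cfg.N), dtype=np.int8)
    Y[: cfg.init_window, : cfg.n_start_context] = 1
    if home_active:
        Y[:, cfg.n_start_context :] = (
            rng.random((T, cfg.n_home_context)) < cfg.poisson_rate
        ).astype(np.int8)
    return Y


def soft_wta_rates(u: np.ndarray, n_active: float) -> np.ndarray:
    """Divisively normalised firing probabilities.

    rho = n_active * softmax(u), clipped below 1: the population's
    expected spike count per step is (approximately) n_active, while the
    relative competition between cells is preserved.
    """
    return np.minimum(n_active * softmax(u), 0.995)


def simulate_sweep(
    cfg: SweepConfig,
    horizon: int,
    rng: np.random.Generator,
    *,
    home_active: bool = True,
) -> tuple[SpikeTrain, np.ndarray]:
    """Simulate one planning event and decode its path.

    ``horizon`` counts the planning steps after the initialisation
    window; the total simulated duration is ``cfg.init_window +
    horizon`` steps.  Returns the spike train (states + context raster)
    and the decoded T x 2 path, with undefined (spike-free) steps
    carried forward from the start location.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    code = cfg.place_code()
    W = gaussian_transition_weights(code, cfg.sigma_trans)
    Theta = sweep_context_weights(cfg, code)
    T = cfg.init_window + horizon
    Y = sweep_context_schedule(cfg, T, rng, home_active=home_active)
    states = np.zeros((T, code.K), dtype=np.int8)
    v_recur = np.zeros(code.K)  # last non-empty activity pattern
    for t in range(T):
        n_prev = v_recur.sum()
        # average the Gaussian kernels of the active cells so the
        # recurrent drive scale does not depend on the spike count; on
        # the rare spike-free step the previous pattern persists, which
        # keeps the activity bump from teleporting to the goal
        u_rec = (W @ v_recur) / n_prev if n_prev > 0 else np.zeros(code.K)
        u = u_rec + Theta @ Y[t]
        rho = soft_wta_rates(u, cfg.n_active)
        v = (rng.random(code.K) < rho).astype(np.int8)
        states[t] = v
        if v.any():
            v_recur = v.astype(float)
    train = SpikeTrain(states=states, contexts=Y, v0=np.zeros(code.K, dtype=np.int8))
    path = decode_trajectory(train, code, initial=np.asarray(cfg.start))
    return train, path


def activity_map(train: SpikeTrain, cfg: SweepConfig) -> np.ndarray:
    """Per-cell spike counts integrated over the event (rows x cols),
    the summed-activity picture of a sweep."""
    return train.states.sum(axis=0).reshape(cfg.rows, cfg.cols)


def write_activity_map(path: str | Path, counts: np.ndarray) -> None:
    pd.DataFrame(counts).to_csv(path, index=False, header=False)
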