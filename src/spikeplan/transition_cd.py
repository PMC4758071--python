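"""Learning the recurrent transition model from demonstrations.

The planner assumes the recurrent weights W encode the one-step state
transition model.  When no analytic model is available, W is acquired
in a pre-learning phase from demonstrated state transitions via
contrastive divergence (CD): for each demonstrated pair
(v_prev, v_next), the positive phase uses the data spikes and the
negative phase a reconstruction sampled from the current conditional
p(v_next | v_prev) = softmax_k(W[k, prev]), giving

    dW[k, i] = eta * ( <nu_next,k nu_prev,i>_data - <nu_hat,k nu_prev,i>_model ).

With one-hot previous states the fixed point of the rule is the
empirical conditional frequency table, which is exactly what the
winner-take-all sampler consumes.

Kinesthetic robot demonstrations are stood in for by a synthetic
generator: smooth Gaussian-increment random walks in the arena,
reflected at its bounds and discretised to the nearest place cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax

from .population import PlaceCode, grid_code

#: Robot-experiment defaults: 15 x 15 place cells over a 70 x 70 cm area.
ROBOT_GRID = (15, 15)
ROBOT_EXTENT = ((0.0, 0.70), (0.0, 0.70))
#: Strong inhibitory context drive injected at planning time on cells
#: overlapping an obstacle (obstacles are not learned).
OBSTACLE_INHIBITION = -10.0


def robot_place_code() -> PlaceCode:
    """The K = 225 place-cell code of the robot arm workspace."""
    return grid_code(*ROBOT_GRID, ROBOT_EXTENT)


@dataclass
class DemoSet:
    """Demonstrated one-step transitions, encoded as place-cell indices.

    ``prev_idx[m] -> next_idx[m]`` is the m-th demonstrated transition;
    ``trajectories`` keeps the continuous source paths (one (L, d)
    array per demonstration) for serialisation.
    """

    prev_idx: np.ndarray
    next_idx: np.ndarray
    code: PlaceCode
    trajectories: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.prev_idx = np.asarray(self.prev_idx, dtype=int)
        self.next_idx = np.asarray(self.next_idx, dtype=int)
        if self.prev_idx.size == 0:
            raise ValueError("demonstration set is empty")
        if self.prev_idx.shape != self.next_idx.shape:
            raise ValueError("prev/next index arrays disagree")
        for arr in (self.prev_idx, self.next_idx):
            if arr.min() < 0 or arr.max() >= self.code.K:
                raise ValueError("demonstration indices outside the place code")

    def __len__(self) -> int:
        return self.prev_idx.size

    def empirical_conditional(self) -> tuple[np.ndarray, np.ndarray]:
        """(P_hat, visits): column i of P_hat is the empirical
        distribution of next cells from cell i; visits counts pairs."""
        K = self.code.K
        counts = np.zeros((K, K))
        np.add.at(counts, (self.next_idx, self.prev_idx), 1.0)
        visits = counts.sum(axis=0)
        with np.errstate(invalid="ignore"):
            P = counts / np.where(visits > 0, visits, 1.0)
        return P, visits


def generate_demonstrations(
    code: PlaceCode,
    n_traj: int,
    step_scale: float,
    rng: np.random.Generator,
    *,
    path_len: int = 50,
) -> DemoSet:
    """Synthetic stand-in for kinesthetic teaching.

    Smooth random 2-D paths: Gaussian increments of standard deviation
    ``step_scale`` (arena units), reflected at the arena bounds, then
    discretised to the nearest preferred position.  Yields
    n_traj * (path_len - 1) transition pairs, deterministic given the
    generator state.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if step_scale <= 0:
        raise ValueError("step_scale must be positive")
    lo, hi = code.lower, code.upper
    span = hi - lo
    prev, nxt, trajs = [], [], []
    for _ in range(n_traj):
        x0 = lo + rng.random(code.d) * span
        steps = rng.normal(scale=step_scale, size=(path_len - 1, code.d))
        path = np.vstack([x0, x0 + np.cumsum(steps, axis=0)])
        # reflect into the arena: fold the unbounded walk at the walls
        folded = np.mod(path - lo, 2 * span)
        path = lo + np.where(folded > span, 2 * span - folded, folded)
        cells = np.array([code.nearest_cell(x) for x in path])
        prev.append(cells[:-1])
        nxt.append(cells[1:])
        trajs.append(path)
    return DemoSet(
        prev_idx=np.concatenate(prev),
        next_idx=np.concatenate(nxt),
        code=code,
        trajectories=trajs,
    )


def cd_learn(
    demos: DemoSet,
    k_steps: int = 1,
    eta: float = 0.5,
    epochs: int = 60,
    rng: np.random.Generator | None = None,
    *,
    W0: np.ndarray | None = None,
    eta_final: float | None = None,
) -> np.ndarray:
    """Contrastive-divergence fit of the recurrent transition weights.

    Batch CD-k: per epoch the data statistics are compared with model
    reconstructions sampled from the current conditional for every
    demonstrated previous state, and each visited column of W moves
    along the (stochastic) likelihood gradient of *its* conditional —
    the positive-minus-negative statistics are normalised by the
    visitation count of the presynaptic state, so rarely and frequently
    visited states converge at the same rate.  ``eta_final`` optionally
    anneals the step size geometrically from ``eta`` to that value over
    the epochs, shrinking the stochastic-reconstruction noise floor.
    Raises on divergence (|w| > 1e3).
    """
    if k_steps < 1:
        raise ValueError("k_steps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    K = demos.code.K
    W = np.zeros((K, K)) if W0 is None else np.array(W0, dtype=float)

    # positive-phase statistics are fixed by the data
    data_counts = np.zeros((K, K))
    np.add.at(data_counts, (demos.next_idx, demos.prev_idx), 1.0)
    prev_states, prev_counts = np.unique(demos.prev_idx, return_counts=True)

    for epoch in range(epochs):
        if eta_final is None or epochs == 1:
            step = eta
        else:
            step = eta * (eta_final / eta) ** (epoch / (epochs - 1))
        model_counts = np.zeros((K, K))
        P = softmax(W, axis=0)
        for i, m in zip(prev_states, prev_counts):
            p = P[:, i]
            for _ in range(k_steps):  # resampling the conditional k times
                draw = rng.multinomial(int(m), p)
            model_counts[:, i] = draw
        diff = data_counts - model_counts
        diff[:, prev_states] /= prev_counts[None, :]
        W += step * diff
        if np.abs(W).max() > 1e3:
            raise RuntimeError(
                f"contrastive divergence diverged at epoch {epoch}: "
                f"max |w| = {np.abs(W).max():.1f} (eta={eta}, n={len(demos)})"
            )
    return W


def learned_conditional(W: np.ndarray) -> np.ndarray:
    """Column-stochastic conditional p(next | prev) implied by W."""
    return softmax(W, axis=0)


def obstacle_bias(
    code: PlaceCode, obstacle_boxes: list[tuple[float, float, float, float]]
) -> np.ndarray:
    """Per-cell planning-time bias: strong inhibition on cells whose
    preferred position falls inside any (x0, y0, x1, y1) obstacle box."""
    bias = np.zeros(code.K)
    for x0, y0, x1, y1 in obstacle_boxes:
        inside = (
            (code.positions[:, 0] >= x0)
            & (code.positions[:, 0] <= x1)
            & (code.positions[:, 1] >= y0)
            & (code.positions[:, 1] <= y1)
        )
        bias[inside] = OBSTACLE_INHIBITION
    return bias


# ---------------------------------------------------------------------------
# DemoSet CSV interchange: (traj_id, t, x, y) in arena units
# ---------------------------------------------------------------------------

def write_demos(path: str | Path, demos: DemoSet) -> None:
    if demos.trajectories is None:
        raise ValueError("this DemoSet has no continuous trajectories to write")
    frames = []
    for tid, traj in enumerate(demos.trajectories):
        df = pd.DataFrame(traj, columns=["x", "y"][: demos.code.d])
        df.insert(0, "t", np.arange(len(traj)))
        df.insert(0, "traj_id", tid)
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_demos(path: str | Path, code: PlaceCode) -> DemoSet:
    """Load demonstrations and re-encode them against ``code``."""
    df = pd.read_csv(path, comment="#")
    cols = [c for c in ("x", "y") if c in df.columns]
    prev, nxt, trajs = [], [], []
    for _, group in df.groupby("traj_id"):
        path_xy = group.sort_values("t")[cols].to_numpy()
        cells = np.array([code.nearest_cell(x) for x in path_xy])
        prev.append(cells[:-1])
        nxt.append(cells[1:])
        trajs.append(path_xy)
    return DemoSet(
        prev_idx=np.concatenate(prev),
        next_idx=np.concatenate(nxt),
        code=code,
        trajectories=trajs,
    )
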