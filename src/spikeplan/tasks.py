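"""Concrete planning environments.

Two benchmark tasks drive the planner:

* a 9-state linear track with a finite horizon, where reward is granted
  only if the agent threads two passages — one at time T/2, one at time
  T — and may move at most one state per step, so success requires
  committing to the passage before the obstacle appears;
* a 15 x 20 grid maze with an infinite-horizon (discounted) objective:
  a uniform 4-neighbour random walk under the prior dynamics, reward
  only at the target cell, episodes capped at T_max = 300 steps and
  discount gamma = 0.98.

Both export the recurrent weight matrix W (the log transition model),
the context schedule, and the reward/termination rules consumed by
:mod:`spikeplan.network` and :mod:`spikeplan.plasticity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.special import softmax

from .network import (
    Activation,
    ContextSchedule,
    NetworkParams,
    SpikeTrain,
    one_hot,
)


# ---------------------------------------------------------------------------
# Finite horizon: the 9-state linear track
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearTrackTask:
    """Passage task on a linear track of K discrete locations.

    The agent starts at ``start_state`` and must occupy ``passage_mid``
    at step T/2 and ``passage_end`` at step T to receive the terminal
    reward.  One context neuron is assigned to each of the T time steps
    (temporal one-hot code), giving the plasticity rule the temporal
    structure needed to time the passages.
    """

    K: int = 9
    T: int = 10
    passage_mid: int = 2
    passage_end: int = 6
    start_state: int = 4
    eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.T < 2 or self.T % 2:
            raise ValueError("T must be even and >= 2")
        if not 0 < self.eps <= 0.01:
            raise ValueError("eps must lie in (0, 0.01]")
        for name in ("passage_mid", "passage_end", "start_state"):
            v = getattr(self, name)
            if not 0 <= v < self.K:
                raise ValueError(f"{name}={v} outside the {self.K}-state track")
        if abs(self.passage_end - self.passage_mid) > self.T // 2:
            raise ValueError("passages unreachable: |mid - end| exceeds T/2 moves")

    @property
    def N(self) -> int:
        return self.T


def track_transition_matrix(task: LinearTrackTask, eps: float | None = None) -> np.ndarray:
    """Row-stochastic transition matrix P[i, k] = p(next=k | current=i).

    Probability mass is split uniformly over the allowed moves
    stay/left/right (|k - i| <= 1, truncated at the boundaries) with an
    ``eps`` leak to every forbidden state, then row-normalised.
    """
    eps = task.eps if eps is None else eps
    K = task.K
    P = np.full((K, K), eps)
    for i in range(K):
        for k in range(max(0, i - 1), min(K, i + 2)):
            P[i, k] = 1.0
    return P / P.sum(axis=1, keepdims=True)


def build_track_weights(task: LinearTrackTask, eps: float | None = None) -> np.ndarray:
    """Recurrent weights W = log P^T so that, with zero context, the WTA
    softmax of column i reproduces the designed transition row exactly."""
    return np.log(track_transition_matrix(task, eps)).T


def track_context_schedule(task: LinearTrackTask) -> ContextSchedule:
    """Temporal one-hot code: context neuron t fires at step t only."""
    return lambda t: one_hot(t, task.T)


def track_reward(train: SpikeTrain, task: LinearTrackTask) -> float:
    """1 iff the trajectory occupies passage_mid at T/2 and passage_end
    at T; the trajectory elsewhere is unconstrained."""
    idx = train.state_indices()
    mid_ok = idx[task.T // 2 - 1] == task.passage_mid
    end_ok = idx[task.T - 1] == task.passage_end
    return float(mid_ok and end_ok)


def track_params(task: LinearTrackTask, *, start_bias: float = 1e3) -> NetworkParams:
    """Untrained network for the track: W from the transition model,
    Theta all zeros (pure random walk before learning), theta0 pinned to
    the start state."""
    theta0 = np.zeros(task.K)
    theta0[task.start_state] = start_bias
    return NetworkParams(
        W=build_track_weights(task),
        Theta=np.zeros((task.K, task.N)),
        theta0=theta0,
        activation=Activation.SOFTMAX_WTA,
    )


# ---------------------------------------------------------------------------
# Infinite horizon: the grid maze
# ---------------------------------------------------------------------------

def default_maze_obstacles(rows: int = 15, cols: int = 20) -> frozenset[tuple[int, int]]:
    """Default obstacle layout: a vertical wall with openings at the top
    and bottom, so exactly two globally optimal routes (over or under
    the wall) connect the default start and target."""
    wall_col = cols // 2
    return frozenset((r, wall_col) for r in range(2, rows - 2))


@dataclass(frozen=True)
class GridMazeTask:
    """Navigation in a rows x cols grid with obstacle cells.

    One state neuron per grid cell (row-major, 0-based indexing); the
    prior dynamics are a uniform walk over the 4-neighbour free cells,
    with illegal moves' mass redistributed to the legal ones.  Reward
    ``r_goal`` is received only at the target cell; an episode ends at
    the target or after ``T_max`` steps.
    """

    rows: int = 15
    cols: int = 20
    obstacles: frozenset[tuple[int, int]] = field(
        default_factory=default_maze_obstacles
    )
    start: tuple[int, int] = (7, 2)
    target: tuple[int, int] = (7, 17)
    T_max: int = 300
    gamma: float = 0.98
    r_goal: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "obstacles", frozenset(map(tuple, self.obstacles)))
        object.__setattr__(self, "start", tuple(self.start))
        object.__setattr__(self, "target", tuple(self.target))
        for cell in (self.start, self.target):
            if not self.in_bounds(cell):
                raise ValueError(f"cell {cell} outside the {self.rows}x{self.cols} grid")
            if cell in self.obstacles:
                raise ValueError(f"cell {cell} is an obstacle")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not maze_connected(self):
            raise ValueError("start and target are not connected through free cells")

    @property
    def K(self) -> int:
        return self.rows * self.cols

    def in_bounds(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.rows and 0 <= c < self.cols

    def is_free(self, cell: tuple[int, int]) -> bool:
        return self.in_bounds(cell) and tuple(cell) not in self.obstacles

    def cell_index(self, cell: tuple[int, int]) -> int:
        r, c = cell
        return r * self.cols + c

    def index_cell(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.cols)

    def neighbors(self, cell: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = cell
        cand = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
        return [x for x in cand if self.is_free(x)]


def maze_adjacency(task: GridMazeTask) -> csr_matrix:
    """Sparse free-cell adjacency (K x K) of the 4-neighbour graph."""
    rows, cols, data = [], [], []
    for r in range(task.rows):
        for c in range(task.cols):
            if not task.is_free((r, c)):
                continue
            i = task.cell_index((r, c))
            for nb in task.neighbors((r, c)):
                rows.append(i)
                cols.append(task.cell_index(nb))
                data.append(1.0)
    return csr_matrix((data, (rows, cols)), shape=(task.K, task.K))


def maze_connected(task: GridMazeTask) -> bool:
    adj = maze_adjacency(task)
    _, labels = connected_components(adj, directed=False)
    return labels[task.cell_index(task.start)] == labels[task.cell_index(task.target)]


def maze_distance_field(task: GridMazeTask) -> np.ndarray:
    """Shortest-path (breadth-first) distance of every free cell to the
    target; +inf for obstacles and unreachable cells."""
    d = shortest_path(
        maze_adjacency(task), method="D", unweighted=True,
        indices=task.cell_index(task.target),
    )
    blocked = np.array(
        [not task.is_free(task.index_cell(i)) for i in range(task.K)]
    )
    d[blocked] = np.inf
    return d


def maze_transition_matrix(task: GridMazeTask) -> np.ndarray:
    """Row-stochastic P[i, k]: uniform over the legal 4-neighbour moves
    out of free cell i (wall/obstacle moves redistributed to legal
    ones).  Obstacle cells get a self-loop to keep P stochastic."""
    P = np.zeros((task.K, task.K))
    for r in range(task.rows):
        for c in range(task.cols):
            i = task.cell_index((r, c))
            if not task.is_free((r, c)):
                P[i, i] = 1.0
                continue
            nbs = task.neighbors((r, c))
            if not nbs:
                P[i, i] = 1.0
                continue
            for nb in nbs:
                P[i, task.cell_index(nb)] = 1.0 / len(nbs)
    return P


def build_maze(
    task: GridMazeTask,
) -> tuple[np.ndarray, Callable[[int], float], Callable[[int], bool]]:
    """Return (W, reward_fn, is_terminal) for the maze.

    W = log P^T with exact zeros floored at a large negative constant so
    all weights stay finite; reward_fn and is_terminal take a state
    index.
    """
    P = maze_transition_matrix(task)
    W = np.log(np.maximum(P, 1e-300)).T
    target = task.cell_index(task.target)

    def reward_fn(state: int) -> float:
        return task.r_goal if state == target else 0.0

    def is_terminal(state: int) -> bool:
        return state == target

    return W, reward_fn, is_terminal


def maze_context_schedule(task: GridMazeTask) -> ContextSchedule:
    """Stationary context: a single always-on neuron, so the learned
    Theta column is a per-state bias field (the 'gradient towards the
    target')."""
    y = np.ones(1, dtype=np.int8)
    return lambda t: y


def maze_params(task: GridMazeTask, *, start_bias: float = 1e3) -> NetworkParams:
    """Untrained maze network: WTA dynamics over 300 cells, one
    always-on context neuron with zero weights, start pinned by theta0."""
    W, _, _ = build_maze(task)
    theta0 = np.zeros(task.K)
    theta0[task.cell_index(task.start)] = start_bias
    return NetworkParams(
        W=W,
        Theta=np.zeros((task.K, 1)),
        theta0=theta0,
        activation=Activation.SOFTMAX_WTA,
    )


def sample_maze_episode(
    params: NetworkParams, task: GridMazeTask, rng: np.random.Generator
) -> tuple[list[int], bool]:
    """Sample one maze episode from the current model.

    Returns the visited state indices (excluding the start cell) and
    whether the target was reached before T_max steps.
    """
    logits = params.W + params.Theta  # N = 1: broadcast bias column
    P = softmax(logits, axis=0)
    cum = np.cumsum(P, axis=0)
    target = task.cell_index(task.target)
    state = task.cell_index(task.start)
    path: list[int] = []
    for _ in range(task.T_max):
        col = cum[:, state]
        state = min(
            int(np.searchsorted(col, rng.random() * col[-1], side="right")),
            task.K - 1,
        )
        path.append(state)
        if state == target:
            return path, True
    return path, False
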