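"""Place-cell population coding of continuous positions.

Each state neuron k owns a preferred position p_k in the arena; a spike
vector decodes to the normalised spike-weighted centroid

    x_hat = sum_k nu_k p_k / sum_k nu_k,

the population-vector readout used for hippocampal place cells.  With a
single spike per step (WTA dynamics) this is just the preferred
position of the winner; with multiple simultaneous spikes it lies in
the convex hull of the active cells' preferred positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import SpikeTrain


@dataclass(frozen=True)
class PlaceCode:
    """Preferred positions of K state neurons in a d-dimensional arena.

    ``positions`` is K x d; ``lower``/``upper`` bound the arena per
    dimension (arena units, e.g. metres).
    """

    positions: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if pos.shape[0] < 1:
            raise ValueError("need at least one place cell")
        if lo.shape != (pos.shape[1],) or hi.shape != (pos.shape[1],):
            raise ValueError("arena bounds must match the position dimension")
        if not np.all(np.isfinite(pos)):
            raise ValueError("preferred positions must be finite")
        if np.any(pos < lo - 1e-12) or np.any(pos > hi + 1e-12):
            raise ValueError("preferred positions must lie inside the arena")

    @property
    def K(self) -> int:
        return self.positions.shape[0]

    @property
    def d(self) -> int:
        return self.positions.shape[1]

    def nearest_cell(self, x: np.ndarray) -> int:
        """Index of the place cell whose preferred position is closest."""
        diff = self.positions - np.asarray(x, dtype=float)
        return int(np.argmin(np.einsum("kd,kd->k", diff, diff)))


def grid_code(
    rows: int,
    cols: int,
    extent: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 2.0), (0.0, 2.0)),
) -> PlaceCode:
    """Place cells on a regular rows x cols grid of cell centres.

    Row-major, 0-based ordering, consistent with grid-maze cell indices:
    neuron r*cols + c sits at the centre of cell (r, c).  Positions are
    (x, y) with x varying along columns and y along rows.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    (x0, x1), (y0, y1) = extent
    dx = (x1 - x0) / cols
    dy = (y1 - y0) / rows
    pos = np.array(
        [
            (x0 + (c + 0.5) * dx, y0 + (r + 0.5) * dy)
            for r in range(rows)
            for c in range(cols)
        ]
    )
    return PlaceCode(positions=pos, lower=np.array([x0, y0]), upper=np.array([x1, y1]))


def decode_position(nu_t: np.ndarray, code: PlaceCode) -> np.ndarray | None:
    """Population-vector decode of one spike vector.

    Returns None (the explicit undefined marker — never a silent zero)
    when no neuron fires; the caller decides how to carry forward.
    """
    nu = np.asarray(nu_t, dtype=float)
    if nu.shape != (code.K,):
        raise ValueError(f"spike vector length {nu.shape} != K={code.K}")
    total = nu.sum()
    if total == 0:
        return None
    return (nu @ code.positions) / total


def decode_trajectory(
    train: SpikeTrain, code: PlaceCode, *, initial: np.ndarray | None = None
) -> np.ndarray:
    """Decode a spike train to a T x d path.

    Steps with no spikes repeat the last defined position; if the very
    first step is undefined, ``initial`` is used as the fallback, and
    its absence is an error.
    """
    if train.K != code.K:
        raise ValueError("spike-train width does not match the place code")
    out = np.empty((train.T, code.d))
    last = None if initial is None else np.asarray(initial, dtype=float)
    n_undefined = 0
    for t in range(train.T):
        x = decode_position(train.states[t], code)
        if x is None:
            n_undefined += 1
            if last is None:
                raise ValueError(
                    "first step has no spikes and no initial position was given"
                )
            x = last
        out[t] = x
        last = x
    if n_undefined:
        import logging

        logging.getLogger(__name__).debug(
            "decode_trajectory: %d/%d undefined steps carried forward",
            n_undefined,
            train.T,
        )
    return out


def write_path_csv(path: str | Path, xy: np.ndarray, *, header: str | None = None) -> None:
    """Write a decoded trajectory as CSV (t, x, y[, ...]) in arena units."""
    xy = np.atleast_2d(xy)
    cols = ["x", "y", "z"][: xy.shape[1]]
    df = pd.DataFrame(xy, columns=cols)
    df.insert(0, "t", np.arange(len(df)))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def read_path_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, comment="#")
    return df.drop(columns=["t"]).to_numpy()
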