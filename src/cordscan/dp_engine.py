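"""Banded dynamic-programming best-path machinery.

All eight anatomical detections in the pipeline reduce to the same problem:
given a per-pixel fitness field ``f[z, y]`` and per-row column bounds
``[y_ant(z), y_post(z)]``, find the continuous top-to-bottom path
(|Delta y| <= 1 between consecutive rows) with maximal cumulative fitness.

The recurrence is

    q[z, y] = 0                                     outside the band
    q[z, y] = f[z, y]                               on the first row
    q[z, y] = max(q[z-1, y-1], q[z-1, y], q[z-1, y+1]) + f[z, y]  otherwise

with a predecessor-offset table ``p`` in {-1, 0, +1} used for backtracking
from the argmax of the last row.

Tie rules (deterministic):
* predecessor ties prefer straight (0), then the anterior diagonal (-1),
  then the posterior diagonal (+1);
* the backtrack start (argmax of the last row) is broken toward smaller y.

Callers must supply fitness fields that are non-negative inside the band so
that the zero value assigned outside the band never beats an in-band path;
the engine asserts this contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .image_model import PathCurve

__all__ = ["FitnessField", "BandBounds", "DpTables",
           "accumulate", "backtrack", "find_best_path"]


@dataclass
class FitnessField:
    """A per-pixel fitness map f[z, y] with a short tag naming the detection."""

    values: np.ndarray
    name: str = "f"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("fitness field must be 2D (z, y)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"fitness field {self.name!r} has non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


class BandBounds:
    """Row range [z_sup, z_inf] plus per-row inclusive column limits.

    ``y_ant`` / ``y_post`` may be scalars, arrays over the full image height,
    or callables of z.  Bounds are clamped to the image width on construction.
    """

    def __init__(self, z_sup: int, z_inf: int,
                 y_ant: int | np.ndarray | Callable[[int], int],
                 y_post: int | np.ndarray | Callable[[int], int],
                 shape: tuple[int, int]):
        nz, ny = shape
        if not (0 <= z_sup <= z_inf < nz):
            raise ValueError(f"invalid row range [{z_sup}, {z_inf}] for height {nz}")
        self.z_sup = int(z_sup)
        self.z_inf = int(z_inf)
        self.shape = (nz, ny)
        zs = np.arange(z_sup, z_inf + 1)
        self.y_ant = np.clip(self._materialize(y_ant, zs), 0, ny - 1).astype(np.int64)
        self.y_post = np.clip(self._materialize(y_post, zs), 0, ny - 1).astype(np.int64)
        if np.any(self.y_ant > self.y_post):
            raise ValueError("empty band: y_ant > y_post on some row after clamping")

    @staticmethod
    def _materialize(spec, zs: np.ndarray) -> np.ndarray:
        if callable(spec):
            return np.asarray([spec(int(z)) for z in zs])
        arr = np.asarray(spec)
        if arr.ndim == 0:
            return np.full(zs.shape, int(arr))
        # an array indexed by absolute z over the whole image
        return arr[zs]

    @property
    def n_rows(self) -> int:
        return self.z_inf - self.z_sup + 1

    def in_band(self, r: int) -> np.ndarray:
        """Boolean in-band indicator for local row r (0-based from z_sup)."""
        ny = self.shape[1]
        ys = np.arange(ny)
        return (ys >= self.y_ant[r]) & (ys <= self.y_post[r])


@dataclass
class DpTables:
    q: np.ndarray  # cumulative fitness, shape (n_rows, ny)
    p: np.ndarray  # predecessor offsets in {-1, 0, +1}, same shape


def accumulate(f: FitnessField, b: BandBounds) -> DpTables:
    """Build the cumulative-fitness and predecessor tables row by row."""
    if f.shape != b.shape:
        raise ValueError("fitness field and band refer to different image shapes")
    ny = f.shape[1]
    n_rows = b.n_rows
    q = np.zeros((n_rows, ny), dtype=np.float64)
    p = np.zeros((n_rows, ny), dtype=np.int8)

    for r in range(n_rows):
        mask = b.in_band(r)
        row_f = f.values[b.z_sup + r]
        if np.any(row_f[mask] < -1e-9):
            raise ValueError(
                f"fitness field {f.name!r} is negative inside the band at row "
                f"{b.z_sup + r}; the engine requires non-negative in-band fitness")
        if r == 0:
            q[0] = np.where(mask, row_f, 0.0)
            continue
        prev = q[r - 1]
        left = np.empty(ny)    # q[z-1, y-1]
        left[0] = 0.0
        left[1:] = prev[:-1]
        right = np.empty(ny)   # q[z-1, y+1]
        right[-1] = 0.0
        right[:-1] = prev[1:]
        best = np.maximum(np.maximum(left, prev), right)
        # tie precedence: straight, then -1, then +1
        off = np.where(prev == best, 0, np.where(left == best, -1, 1)).astype(np.int8)
        q[r] = np.where(mask, best + row_f, 0.0)
        p[r] = np.where(mask, off, 0)
    return DpTables(q=q, p=p)


def backtrack(t: DpTables, b: BandBounds) -> PathCurve:
    """Recover the best path from the tables (ties start at the smallest y)."""
    n_rows = b.n_rows
    last = t.q[n_rows - 1].copy()
    outside = ~b.in_band(n_rows - 1)
    last[outside] = -np.inf
    y = int(np.argmax(last))  # np.argmax returns the first (smallest-y) maximum
    values = np.empty(n_rows, dtype=np.int64)
    values[-1] = y
    for r in range(n_rows - 1, 0, -1):
        y = y + int(t.p[r, y])
        y = min(max(y, 0), b.shape[1] - 1)
        values[r - 1] = y
    return PathCurve(b.z_sup, b.z_inf, values)


def find_best_path(f: FitnessField, b: BandBounds) -> PathCurve:
    """Convenience composition of :func:`accumulate` and :func:`backtrack`."""
    return backtrack(accumulate(f, b), b)
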