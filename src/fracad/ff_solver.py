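"""Explicit fractal-fractional Adams-Bashforth product-integration solver.

Solves the Caputo-sense fractal-fractional initial value problem in its
equivalent weakly singular Volterra form

    Y(t) = Y0 + (q / Gamma(p)) * Int_0^t s^(q-1) (t-s)^(p-1) h(s, Y(s)) ds,

with fractional order 0 < p <= 1 and fractal dimension 0 < q <= 1.  The
integrand g(s) = s^(q-1) h(s, Y(s)) is replaced on each panel
[t_n, t_{n+1}] by its two-point Lagrange interpolant through the trailing
nodes t_n and t_{n-1}; integrating the interpolant against the power-law
kernel exactly gives the closed-form weight pair

    wA(m, n, p) = (m+p+2-n)(1+m-n)^p - (m+2p+2-n)(m-n)^p,
    wB(m, n, p) = (m+1-n)^(p+1) - (m+1+p-n)(m-n)^p,

and the explicit update

    Y_{m+1} = Y0 + q l^p / Gamma(p+2)
              * Sum_{n=0}^{m} [ g_n h(t_n, Y_n) wA - g_{n-1} h(t_{n-1}, Y_{n-1}) wB ],

where g_k = t_k^(q-1) and l is the uniform step.  At p = q = 1 the weights
collapse to (3, 1), the prefactor to l/2, and the scheme is algebraically
the cumulative classical two-step Adams-Bashforth method.

Two regularizations are needed to make the scheme well defined on the
grid (documented as this package's own choices; see docs/methods.md):

* the factor t_0^(q-1) is infinite at t_0 = 0 when q < 1, so the factor
  for node 0 (and for the virtual history node -1) is evaluated at the
  first positive node, g_0 := t_1^(q-1);
* the n = 0 term of the memory sum references the off-grid point
  (t_{-1}, Y_{-1}), which is supplied by constant extrapolation
  (t_{-1}, Y_{-1}) := (t_0, Y_0).  This keeps the rule exact for constant
  integrands.

The memory sum is recomputed from Y0 at every step (O(N^2) total work),
following the cumulative form of the update.  There is no randomness and
summation order is fixed, so identical inputs give bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import SPECIES

__all__ = [
    "FFOrder",
    "TimeGrid",
    "Trajectory",
    "WeightPair",
    "ab_weight_pair",
    "fractal_factor",
    "solve_ff",
    "classical_ab2",
    "write_trajectory",
    "read_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FFOrder:
    """Fractional order p and fractal dimension q, both in (0, 1]."""

    p: float = 1.0
    q: float = 1.0

    def __post_init__(self) -> None:
        p, q = float(self.p), float(self.q)
        if not (0.0 < p <= 1.0) or not (0.0 < q <= 1.0):
            raise ValueError(
                f"fractional order and fractal dimension must lie in (0, 1], "
                f"got p={p!r}, q={q!r}"
            )
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid t_n = n*l for n = 0..n_steps, in years."""

    step: float
    n_steps: int

    def __post_init__(self) -> None:
        if not (float(self.step) > 0) or not np.isfinite(self.step):
            raise ValueError(f"step must be positive and finite, got {self.step!r}")
        if int(self.n_steps) < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps!r}")
        object.__setattr__(self, "step", float(self.step))
        object.__setattr__(self, "n_steps", int(self.n_steps))

    @classmethod
    def from_horizon(cls, step: float, horizon: float) -> "TimeGrid":
        """Grid covering [0, horizon] with the given step (horizon = n*l)."""
        n = int(round(horizon / step))
        if abs(n * step - horizon) > 1e-9 * max(1.0, horizon):
            raise ValueError(
                f"horizon {horizon} is not an integer multiple of step {step}"
            )
        return cls(step=step, n_steps=n)

    @property
    def horizon(self) -> float:
        return self.n_steps * self.step

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.step


@dataclass(frozen=True)
class Trajectory:
    """States on a uniform time grid: ``states[n]`` at ``grid.nodes[n]``."""

    grid: TimeGrid
    states: np.ndarray  # shape (n_steps + 1, dim)
    columns: tuple = field(default=SPECIES)

    def __post_init__(self) -> None:
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if states.shape[0] != self.grid.n_steps + 1:
            raise ValueError(
                f"expected {self.grid.n_steps + 1} states, got {states.shape[0]}"
            )
        states.setflags(write=False)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "columns", tuple(self.columns)[: states.shape[1]])

    @property
    def times(self) -> np.ndarray:
        return self.grid.nodes

    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.columns))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class WeightPair:
    """Coefficients multiplying the current (wA) and previous (wB) node."""

    wA: float
    wB: float


def _weight_arrays(m: int, p: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (wA, wB) for n = 0..m at step index m, via k = m - n."""
    k = np.arange(m, -1, -1, dtype=float)  # k[n] = m - n
    kp = k**p          # 0^p = 0 for p > 0
    k1 = k + 1.0
    k1p = k1**p
    wA = (k + p + 2.0) * k1p - (k + 2.0 * p + 2.0) * kp
    wB = k1**(p + 1.0) - (k + 1.0 + p) * kp
    return wA, wB


def ab_weight_pair(m: int, n: int, p: float) -> WeightPair:
    """The two closed-form product-integration weights at (m, n).

    ``wA`` multiplies the integrand at node n, ``wB`` at node n-1.  For
    p = 1 the pair is (3, 1) for every (m, n); for n = m it is (p+2, 1).
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"fractional order must lie in (0, 1], got {p!r}")
    if not (0 <= n <= m):
        raise ValueError(f"need 0 <= n <= m, got n={n}, m={m}")
    k = float(m - n)
    kp = k**p
    wA = (k + p + 2.0) * (k + 1.0)**p - (k + 2.0 * p + 2.0) * kp
    wB = (k + 1.0)**(p + 1.0) - (k + 1.0 + p) * kp
    return WeightPair(wA=wA, wB=wB)


def fractal_factor(n: int, grid: TimeGrid, q: float) -> float:
    """The fractal weight t_n^(q-1) of node n, regularized at the origin.

    Returns exactly 1.0 for every node when q = 1.  For q < 1 the value
    at n = 0 (and at the virtual history node n = -1) would be infinite,
    so it is replaced by the factor of the first positive node,
    t_1^(q-1).
    """
    if n < -1:
        raise ValueError(f"node index must be >= -1, got {n}")
    if q == 1.0:
        return 1.0
    t = grid.step * max(n, 1)
    return t**(q - 1.0)


def _as_initial_array(y0) -> tuple[np.ndarray, bool]:
    if hasattr(y0, "as_array"):
        return y0.as_array(), False
    arr = np.atleast_1d(np.asarray(y0, dtype=float))
    scalar = np.ndim(y0) == 0
    return arr, scalar


def solve_ff(rhs: Callable[[float, np.ndarray], np.ndarray],
             y0,
             grid: TimeGrid,
             order: FFOrder) -> Trajectory:
    """Integrate ``y' (fractal-fractional) = rhs(t, y)`` on the grid.

    ``rhs`` maps ``(t, y)`` to the derivative array; ``y0`` may be a
    scalar, an array, or a StateVector-like object with ``as_array()``.
    Raises ``FloatingPointError`` (with the step index) if the state
    becomes non-finite.
    """
    p, q = order.p, order.q
    l = grid.step
    N = grid.n_steps
    t = grid.nodes
    y0_arr, _ = _as_initial_array(y0)
    dim = y0_arr.size

    Y = np.empty((N + 1, dim), dtype=float)
    Y[0] = y0_arr
    if N == 0:
        return Trajectory(grid=grid, states=Y)

    # g[n] = fractal factor at node n (g[0] regularized; history node
    # n = -1 shares g[0] by construction).
    if q == 1.0:
        g = np.ones(N + 1)
    else:
        g = np.empty(N + 1)
        g[0] = (l * 1.0)**(q - 1.0)
        g[1:] = (t[1:])**(q - 1.0)

    pref = q * l**p / math.gamma(p + 2.0)

    F = np.empty((N + 1, dim), dtype=float)  # F[n] = g_n * h(t_n, Y_n)
    F[0] = g[0] * np.asarray(rhs(t[0], Y[0]), dtype=float)

    warned_negative = False
    for m in range(N):
        wA, wB = _weight_arrays(m, p)
        # F_{n-1} for n = 0..m, with the n = 0 history term frozen at F_0.
        incr = wA @ F[: m + 1]
        incr -= wB[0] * F[0]
        if m >= 1:
            incr -= wB[1:] @ F[:m]
        Y[m + 1] = Y[0] + pref * incr
        if not np.all(np.isfinite(Y[m + 1])):
            raise FloatingPointError(
                f"state became non-finite at step {m + 1} (t = {t[m + 1]:g})"
            )
        if not warned_negative and np.any(Y[m + 1] < 0):
            logger.warning(
                "population went negative at step %d (t = %g years); the "
                "model is linear and unclamped", m + 1, t[m + 1],
            )
            warned_negative = True
        F[m + 1] = g[m + 1] * np.asarray(rhs(t[m + 1], Y[m + 1]), dtype=float)

    return Trajectory(grid=grid, states=Y)


def classical_ab2(rhs: Callable[[float, np.ndarray], np.ndarray],
                  y0,
                  grid: TimeGrid) -> Trajectory:
    """Cumulative classical two-step Adams-Bashforth reference.

    Y_{m+1} = Y0 + (l/2) * Sum_{n=0}^{m} (3 h_n - h_{n-1}), with the
    history term h_{-1} := h_0 (so the first step is the explicit Euler
    starter).  This is the p = q = 1 reduction of :func:`solve_ff` and
    serves as its integer-order oracle.
    """
    l = grid.step
    N = grid.n_steps
    t = grid.nodes
    y0_arr, _ = _as_initial_array(y0)
    dim = y0_arr.size

    Y = np.empty((N + 1, dim), dtype=float)
    Y[0] = y0_arr
    if N == 0:
        return Trajectory(grid=grid, states=Y)

    H = np.empty((N + 1, dim), dtype=float)
    H[0] = np.asarray(rhs(t[0], Y[0]), dtype=float)
    acc = np.zeros(dim)
    for m in range(N):
        h_prev = H[m - 1] if m >= 1 else H[0]
        acc = acc + (3.0 * H[m] - h_prev)
        Y[m + 1] = Y[0] + (l / 2.0) * acc
        H[m + 1] = np.asarray(rhs(t[m + 1], Y[m + 1]), dtype=float)
    return Trajectory(grid=grid, states=Y)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (header ``time,R,Q,...``), full precision.

    Values are serialized with ``repr`` round-trip precision so that
    :func:`read_trajectory` reproduces the in-memory doubles exactly.
    """
    with open(path, "w", newline="") as fh:
        fh.write("time," + ",".join(traj.columns) + "\n")
        for ti, row in zip(traj.times, traj.states):
            fh.write(repr(float(ti)) + ","
                     + ",".join(repr(float(v)) for v in row) + "\n")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    times = df["time"].to_numpy(dtype=float)
    if len(times) == 1:
        step = 1.0  # degenerate single-node trajectory; step is arbitrary
    else:
        step = times[1] - times[0]
    grid = TimeGrid(step=step, n_steps=len(times) - 1)
    return Trajectory(grid=grid,
                      states=df.iloc[:, 1:].to_numpy(dtype=float),
                      columns=tuple(df.columns[1:]))
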