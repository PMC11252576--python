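"""Independent reference solutions used to validate the solver.

Each oracle covers a corner of the (p, q) parameter square by a route
that shares no code with the product-integration scheme:

* ``expm_solution`` — matrix exponential, exact for the integer-order
  limit p = q = 1 of any linear system;
* ``mittag_leffler`` — the one-parameter Mittag-Leffler function
  E_p(z), whose scaled form y0 * E_p(lambda * t^p) solves the scalar
  linear Caputo equation at q = 1;
* ``power_forcing_exact`` — Beta-function closed form of the Volterra
  integral for power-law forcing c * t^a, valid for every (p, q);
* ``fine_grid_reference`` — the solver itself on a much finer grid,
  subsampled to the coarse nodes, for self-convergence checks at
  general (p, q) where no closed form exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import expm
from scipy.special import beta as beta_fn

from .ff_solver import FFOrder, TimeGrid, Trajectory, solve_ff
from .model import LinearModel

__all__ = [
    "PowerForcingSpec",
    "expm_solution",
    "mittag_leffler",
    "power_forcing_exact",
    "fine_grid_reference",
]

#: beyond this |z| the double-precision series suffers cancellation;
#: escalate to arbitrary precision.
_SERIES_ESCALATION = 30.0
_MAX_TERMS = 10_000


@dataclass(frozen=True)
class PowerForcingSpec:
    """Forcing h(t) = c * t^a with initial value y0; requires a >= 0."""

    c: float
    a: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"forcing exponent must be >= 0, got {self.a!r}")

    def rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        c, a = self.c, self.a
        if a == 0.0:
            return lambda t, y: np.full_like(np.atleast_1d(y), c, dtype=float)
        return lambda t, y: np.full_like(np.atleast_1d(y), c * t**a, dtype=float)


def expm_solution(M: LinearModel | np.ndarray, y0, times) -> Trajectory:
    """Exact integer-order solution y(t) = exp(M t) @ y0 at the nodes.

    ``times`` may be a :class:`TimeGrid` or a uniform array of nodes
    starting at 0.
    """
    A = M.M if isinstance(M, LinearModel) else np.asarray(M, dtype=float)
    if isinstance(times, TimeGrid):
        grid = times
    else:
        times = np.asarray(times, dtype=float)
        grid = TimeGrid(step=times[1] - times[0] if len(times) > 1 else 1.0,
                        n_steps=len(times) - 1)
    y0_arr = y0.as_array() if hasattr(y0, "as_array") else \
        np.atleast_1d(np.asarray(y0, dtype=float))
    # propagate step by step with a single per-step propagator: the grid
    # is uniform, so exp(M t_n) = P^n with P = exp(M l).
    P = expm(A * grid.step)
    states = np.empty((grid.n_steps + 1, y0_arr.size))
    states[0] = y0_arr
    for n in range(1, grid.n_steps + 1):
        states[n] = P @ states[n - 1]
    return Trajectory(grid=grid, states=states)


def mittag_leffler(z: float, p: float, tol: float = 1e-14) -> float:
    """One-parameter Mittag-Leffler function E_p(z) for real z, 0 < p <= 1.

    Evaluated by its power series sum_k z^k / Gamma(p k + 1), truncated
    when a term falls below ``tol`` relative to the partial sum.  For
    |z| > 30 the alternating series loses all double precision to
    cancellation, so evaluation escalates to 50-digit arbitrary
    precision arithmetic.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"order must lie in (0, 1], got {p!r}")
    z = float(z)
    if z == 0.0:
        return 1.0
    if abs(z) > _SERIES_ESCALATION:
        return _mittag_leffler_mp(z, p)
    total = 1.0
    term = 1.0
    for k in range(1, _MAX_TERMS):
        term = z**k / math.gamma(p * k + 1.0)
        total += term
        if abs(term) < tol * max(1.0, abs(total)):
            return total
    raise ArithmeticError(
        f"Mittag-Leffler series did not converge within {_MAX_TERMS} terms "
        f"for z={z}, p={p}"
    )


def _mittag_leffler_mp(z: float, p: float) -> float:
    import mpmath

    # the largest series term is ~exp(|z|^(1/p)); carry enough digits to
    # survive the cancellation down to the O(1) result
    dps = 35 + int(1.2 * abs(z)**(1.0 / p) / math.log(10.0))
    with mpmath.workdps(dps):
        zz = mpmath.mpf(z)
        total = mpmath.mpf(1)
        term = mpmath.mpf(1)
        for k in range(1, 20 * _MAX_TERMS):
            term = zz**k / mpmath.gamma(p * k + 1)
            total += term
            if abs(term) < mpmath.mpf("1e-30") * max(1, abs(total)):
                return float(total)
    raise ArithmeticError(
        f"high-precision Mittag-Leffler series did not converge for z={z}, p={p}"
    )


def power_forcing_exact(spec: PowerForcingSpec, order: FFOrder, t) -> float | np.ndarray:
    """Exact solution of the Volterra form for power-law forcing.

    For h(s) = c * s^a the fractal-fractional integral evaluates in
    closed form through the Beta integral
    Int_0^t s^(mu-1) (t-s)^(p-1) ds = B(mu, p) t^(mu+p-1):

        y(t) = y0 + c * (q / Gamma(p)) * B(q + a, p) * t^(p + q + a - 1).
    """
    p, q = order.p, order.q
    c, a, y0 = spec.c, spec.a, spec.y0
    t = np.asarray(t, dtype=float)
    coeff = c * (q / math.gamma(p)) * beta_fn(q + a, p)
    expo = p + q + a - 1.0
    # at t = 0 the integral vanishes regardless of the (possibly zero
    # or negative) exponent
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.where(t == 0.0, y0, y0 + coeff * t**expo)
    return float(val) if val.ndim == 0 else val


def fine_grid_reference(rhs: Callable[[float, np.ndarray], np.ndarray],
                        y0,
                        order: FFOrder,
                        grid: TimeGrid,
                        l_ref: float) -> Trajectory:
    """Solver output on a refined grid, subsampled to the coarse nodes.

    ``l_ref`` must divide the coarse step exactly (an integer number of
    fine steps per coarse step).  A reference computed at the same step
    as the target grid is the identity.
    """
    ratio = grid.step / l_ref
    r = int(round(ratio))
    if r < 1 or abs(ratio - r) > 1e-9:
        raise ValueError(
            f"reference step {l_ref} must evenly divide the coarse step {grid.step}"
        )
    fine = TimeGrid(step=grid.step / r, n_steps=grid.n_steps * r)
    traj = solve_ff(rhs, y0, fine, order)
    return Trajectory(grid=grid, states=traj.states[::r], columns=traj.columns)
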