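"""Seven-population Alzheimer's disease crosstalk model.

The model tracks seven interacting brain-cell/fibril populations —
proliferative reactive astrocytes (R), quiescent astrocytes (Q),
aggregation-prone amyloid-beta fibrils (Abeta), pro- and anti-inflammatory
activated microglia (Ip, Ia), and surviving/dead neurons (S, D) — coupled
through sixteen signed crosstalk pathways plus an amyloid clearance rate.
All pathways are linear, so the right-hand side is a constant 7x7 rate
matrix acting on the state.

Three population pairs (R/Q, Ip/Ia, S/D) obey exactly antisymmetric
equations: a cell leaving one member of a pair enters the other, so the
pair totals R+Q, Ip+Ia and S+D are conserved for all time.  This exact
structure is preserved at the floating-point level: the paired rows of the
rate matrix are bitwise negations of each other, and the vector field is
evaluated as a single matrix product so that paired components of every
derivative are exact negations too.

Units: time in years, rates in 1/year, populations are dimensionless
cell/fibril counts.  Populations are not clamped at zero — the model is
linear and unclamped; the solver warns if a component goes negative.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Iterator

import numpy as np

__all__ = [
    "SPECIES",
    "ADParameters",
    "StateVector",
    "LinearModel",
    "default_parameters",
    "default_initial_state",
    "rhs",
    "as_matrix",
    "conserved_sums",
    "vector_field",
]

#: Component order used everywhere (state vectors, matrix rows, CSV columns).
SPECIES = ("R", "Q", "Abeta", "Ip", "Ia", "S", "D")

_RATE_NAMES = tuple(f"lambda{i}" for i in range(1, 17)) + ("lambdaR",)


@dataclass(frozen=True)
class ADParameters:
    """The seventeen pathway rates of the crosstalk network (1/year).

    ``lambda1`` .. ``lambda16`` are the signed activation/suppression
    pathways between populations; ``lambdaR`` is the amyloid-beta
    clearance (self-decay) rate.  Defaults are the published reference
    values.  All rates must be finite and non-negative.
    """

    lambda1: float = 1e-5   # Q -> S
    lambda2: float = 1e-3   # R -> D
    lambda3: float = 1e-2   # Ip -> D
    lambda4: float = 1e-4   # Ia -> Q
    lambda5: float = 1e-2   # Ip -> R
    lambda6: float = 1e-2   # S -> Ia
    lambda7: float = 1e-4   # Q -> Ia
    lambda8: float = 1e-2   # Abeta _|_ Ia
    lambda9: float = 1e-2   # Ip _|_ Ia
    lambda10: float = 1e-2  # D -> Ip
    lambda11: float = 1e-2  # S _|_ Ip
    lambda12: float = 1e-4  # Q _|_ Ip
    lambda13: float = 1e-2  # Abeta -> Ia
    lambda14: float = 1e-4  # Ia _|_ Ip
    lambda15: float = 1.0   # S -> Abeta
    lambda16: float = 1e-2  # Ia _|_ Abeta
    lambdaR: float = 1.0    # Abeta clearance

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"rate {f.name} must be finite and >= 0, got {v!r}"
                )
            object.__setattr__(self, f.name, v)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ADParameters":
        unknown = set(mapping) - set(_RATE_NAMES)
        if unknown:
            raise ValueError(f"unknown rate names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class StateVector:
    """One snapshot of the seven populations (dimensionless counts)."""

    R: float
    Q: float
    Abeta: float
    Ip: float
    Ia: float
    S: float
    D: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"state component {name} is not finite: {v!r}")
            object.__setattr__(self, name, v)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"expected 7 components, got shape {arr.shape}")
        return cls(*arr.tolist())

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


@dataclass(frozen=True)
class LinearModel:
    """The 7x7 rate matrix M (1/year) with M @ y == rhs(y).

    Row/column order follows :data:`SPECIES`.  The Q, Ia and D rows are
    exact elementwise negations of the R, Ip and S rows, so the three
    pair sums are conserved exactly.
    """

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (7, 7):
            raise ValueError(f"rate matrix must be 7x7, got {M.shape}")
        M = M.copy()
        M.setflags(write=False)
        object.__setattr__(self, "M", M)

    def __matmul__(self, y) -> np.ndarray:
        return self.M @ np.asarray(y, dtype=float)


def default_parameters() -> ADParameters:
    """The published reference rates (1/year)."""
    return ADParameters()


def default_initial_state() -> StateVector:
    """The reference initial populations used throughout the simulations."""
    return StateVector(R=1e3, Q=1e5, Abeta=1e3, Ip=1e3, Ia=1e5, S=1e4, D=1e2)


def as_matrix(params: ADParameters | None = None) -> LinearModel:
    """Assemble the rate matrix of the crosstalk system.

    The R, Ip and S rows are built first and the paired Q, Ia and D rows
    are set to their exact negations, making pairwise conservation a
    bitwise property of the matrix rather than an approximate one.
    """
    if params is None:
        params = default_parameters()
    la = params
    M = np.zeros((7, 7), dtype=float)
    i = {name: k for k, name in enumerate(SPECIES)}

    # dR/dt = la5*Ip - la4*Ia
    M[i["R"], i["Ip"]] = la.lambda5
    M[i["R"], i["Ia"]] = -la.lambda4
    # dAbeta/dt = -laR*Abeta - la16*Ia + la15*S
    M[i["Abeta"], i["Abeta"]] = -la.lambdaR
    M[i["Abeta"], i["Ia"]] = -la.lambda16
    M[i["Abeta"], i["S"]] = la.lambda15
    # dIp/dt = -(la7+la12)*Q + (la8+la13)*Abeta + la9*Ip - la14*Ia
    #          - (la6+la11)*S + la10*D
    M[i["Ip"], i["Q"]] = -(la.lambda7 + la.lambda12)
    M[i["Ip"], i["Abeta"]] = la.lambda8 + la.lambda13
    M[i["Ip"], i["Ip"]] = la.lambda9
    M[i["Ip"], i["Ia"]] = -la.lambda14
    M[i["Ip"], i["S"]] = -(la.lambda6 + la.lambda11)
    M[i["Ip"], i["D"]] = la.lambda10
    # dS/dt = -la2*R + la1*Q - la3*Ip
    M[i["S"], i["R"]] = -la.lambda2
    M[i["S"], i["Q"]] = la.lambda1
    M[i["S"], i["Ip"]] = -la.lambda3

    # Paired equations are exact negations: Q of R, Ia of Ip, D of S.
    M[i["Q"]] = -M[i["R"]]
    M[i["Ia"]] = -M[i["Ip"]]
    M[i["D"]] = -M[i["S"]]
    return LinearModel(M)


def rhs(state: StateVector | np.ndarray,
        params: ADParameters | None = None) -> np.ndarray:
    """Evaluate the vector field (h1..h7) at a state, in counts/year.

    Computed as a single matrix product with the rate matrix of
    :func:`as_matrix`, so the pairwise antisymmetries h1 = -h2,
    h4 = -h5 and h6 = -h7 hold exactly in floating point.
    """
    y = state.as_array() if isinstance(state, StateVector) else \
        np.asarray(state, dtype=float)
    if y.shape != (7,):
        raise ValueError(f"state must have 7 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite components")
    return as_matrix(params).M @ y


def vector_field(params: ADParameters | None = None
                 ) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return an autonomous ``f(t, y)`` callable for the solver."""
    M = as_matrix(params).M

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return M @ y

    return f


def conserved_sums(state) -> tuple[float, float, float]:
    """The three conserved pair totals ``(R+Q, Ip+Ia, S+D)``.

    Accepts a :class:`StateVector`, a length-7 array, or a 2-D array of
    states (one row per time node), in which case three arrays return.
    """
    y = state.as_array() if isinstance(state, StateVector) else \
        np.asarray(state, dtype=float)
    if y.ndim == 1:
        return (y[0] + y[1], y[3] + y[4], y[5] + y[6])
    return (y[..., 0] + y[..., 1], y[..., 3] + y[..., 4], y[..., 5] + y[..., 6])
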