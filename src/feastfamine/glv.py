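"""Generalized Lotka-Volterra batch dynamics with fixed-biomass resampling.

Interactions here are direct and pairwise (dx_i/dt = x_i(r_i + Σ a_ij x_j)),
not resource-mediated.  At the end of every batch of duration ``T`` the
community is resampled: the next batch starts from total biomass ``B0`` with
the relative abundances of the previous batch's endpoint.  For two species
this composition reduces to a one-dimensional discrete map on the fraction of
species 2, which can undergo a period-doubling route to chaos for suitable
predator-prey-type coefficient sets.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .chaos import BifurcationDiagram, bifurcation_scan
from .errors import CommunityExtinctError, ConfigError, IntegrationError, InvalidStateError

__all__ = [
    "GLVParams",
    "glv_rhs",
    "apply_resampling",
    "fraction_map",
    "scan_glv",
    "load_glv_params",
    "save_glv_params",
    "glv_preset",
]

#: fractions within this distance of 0 or 1 snap to the boundary (extinction
#: absorption for the reduced map)
BOUNDARY_EPS = 1e-15


@dataclasses.dataclass(frozen=True)
class GLVParams:
    """Two-species gLV rates, interaction matrix, and resampling protocol.

    ``A[i][j]`` is the per-biomass effect of species j on species i
    (1/(biomass·day)); ``B0`` the fixed total biomass restored at each
    resampling; ``T`` the batch duration in days.
    """

    r1: float
    r2: float
    A: tuple  #: 2x2 nested tuple ((a11, a12), (a21, a22))
    B0: float = 1.0
    T: float = 10.0

    def __post_init__(self):
        A = tuple(tuple(float(v) for v in row) for row in self.A)
        if len(A) != 2 or any(len(row) != 2 for row in A):
            raise ConfigError("A must be a 2x2 matrix")
        if not all(math.isfinite(v) for row in A for v in row):
            raise ConfigError("A must be finite")
        object.__setattr__(self, "A", A)
        if not (math.isfinite(self.r1) and math.isfinite(self.r2)):
            raise ConfigError("rates must be finite")
        if not self.B0 > 0:
            raise ConfigError(f"B0 must be > 0, got {self.B0}")
        if not self.T > 0:
            raise ConfigError(f"T must be > 0, got {self.T}")

    @property
    def a_matrix(self) -> np.ndarray:
        return np.asarray(self.A, dtype=float)

    def replace(self, **changes) -> "GLVParams":
        return dataclasses.replace(self, **changes)

    def replace_coeff(self, name: str, value: float) -> "GLVParams":
        """Return a copy with one of r1, r2, a11, a12, a21, a22, B0, T changed."""
        if name in ("r1", "r2", "B0", "T"):
            return self.replace(**{name: float(value)})
        if name in ("a11", "a12", "a21", "a22"):
            i, j = int(name[1]) - 1, int(name[2]) - 1
            A = [list(row) for row in self.A]
            A[i][j] = float(value)
            return self.replace(A=tuple(tuple(row) for row in A))
        raise ConfigError(f"unknown gLV coefficient {name!r}")

    def to_dict(self) -> dict:
        return {"r1": self.r1, "r2": self.r2, "A": [list(r) for r in self.A],
                "B0": self.B0, "T": self.T}

    @classmethod
    def from_dict(cls, d: dict) -> "GLVParams":
        known = {"r1", "r2", "A", "B0", "T"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown GLVParams keys: {sorted(unknown)}")
        return cls(r1=float(d["r1"]), r2=float(d["r2"]),
                   A=tuple(tuple(float(v) for v in row) for row in d["A"]),
                   B0=float(d.get("B0", 1.0)), T=float(d.get("T", 10.0)))


def load_glv_params(path) -> GLVParams:
    with open(path) as fh:
        return GLVParams.from_dict(json.load(fh))


def save_glv_params(params: GLVParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
        fh.write("\n")


def glv_preset(name: str) -> GLVParams:
    """Shipped coefficient sets: 'stable', 'limit_cycle', or 'chaotic'.

    Synthetic reference sets found by grid search over predator-prey-type
    (a12·a21 < 0) coefficients; frozen as package data.
    """
    import importlib.resources as res

    path = res.files("feastfamine.data").joinpath(f"glv_{name}_params.json")
    try:
        with path.open() as fh:
            return GLVParams.from_dict(json.load(fh))
    except FileNotFoundError:
        raise ConfigError(f"unknown gLV preset {name!r}") from None


def glv_rhs(x: Sequence[float], params: GLVParams) -> np.ndarray:
    """dx_i/dt = x_i (r_i + Σ_j a_ij x_j)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidStateError(f"non-finite gLV state {x}")
    r = np.array([params.r1, params.r2])
    return x * (r + params.a_matrix @ x)


def _glv_rhs_ode(t, x, r, A):
    xc = np.maximum(x, 0.0)
    return xc * (r + A @ xc)


def _integrate_glv(x0: np.ndarray, params: GLVParams, duration: float) -> np.ndarray:
    r = np.array([params.r1, params.r2])
    A = params.a_matrix
    sol = solve_ivp(
        _glv_rhs_ode, (0.0, duration), x0, args=(r, A),
        method="LSODA", rtol=1e-10, atol=1e-12, t_eval=(duration,),
    )
    if not sol.success:
        raise IntegrationError(
            f"gLV batch integration failed from x0={x0.tolist()}: {sol.message}",
            last_valid_time=float(sol.t[-1]) if sol.t.size else 0.0,
        )
    y = sol.y[:, -1]
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"gLV batch blew up from x0={x0.tolist()}")
    return np.maximum(y, 0.0)


def apply_resampling(x_end: Sequence[float], B0: float) -> np.ndarray:
    """Project a batch endpoint onto total biomass B0 at unchanged proportions."""
    x = np.asarray(x_end, dtype=float)
    if np.any(x < 0):
        raise InvalidStateError(f"negative biomass {x}")
    total = float(x.sum())
    if total <= 0:
        raise CommunityExtinctError("total biomass is zero; community extinct")
    return B0 * (x / total)


def fraction_map(f: float, params: GLVParams) -> float:
    """One-dimensional reduction of the batch-plus-resampling composition.

    Starts a batch from (B0·(1-f), B0·f), integrates for T days and returns
    the species-2 fraction at the batch end.  The boundaries f = 0 and f = 1
    are absorbing (a species absent at inoculation cannot appear).
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigError(f"fraction must be in [0, 1], got {f}")
    if f <= BOUNDARY_EPS:
        return 0.0
    if f >= 1.0 - BOUNDARY_EPS:
        return 1.0
    x0 = np.array([params.B0 * (1.0 - f), params.B0 * f])
    y = _integrate_glv(x0, params, params.T)
    total = float(y.sum())
    if total <= 0:
        raise CommunityExtinctError(f"community extinct within batch from f={f}")
    out = float(y[1] / total)
    if out <= BOUNDARY_EPS:
        return 0.0
    if out >= 1.0 - BOUNDARY_EPS:
        return 1.0
    return out


def scan_glv(
    params: GLVParams,
    scan_param: str = "a21",
    scan_grid: Sequence[float] = (),
    n_transient: int = 200,
    n_keep: int = 100,
    f0: float = 0.3,
    with_lyapunov: bool = False,
    lyapunov_iter: int = 400,
) -> BifurcationDiagram:
    """Bifurcation scan of the 1-D fraction map over one coefficient (or T).

    For each grid value the named coefficient is replaced, the map iterated
    from ``f0``, ``n_transient`` iterates discarded and ``n_keep`` kept.
    """
    grid = np.asarray(scan_grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("scan grid must be nonempty")

    def factory(value: float):
        p = params.replace_coeff(scan_param, value)
        return lambda f: fraction_map(f, p)

    return bifurcation_scan(
        factory, grid, n_transient=n_transient, n_keep=n_keep, x0=f0,
        with_lyapunov=with_lyapunov, lyapunov_iter=lyapunov_iter,
    )
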