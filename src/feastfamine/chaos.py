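"""Chaos diagnostics for discrete maps: largest Lyapunov exponent (Benettin
two-trajectory method), period detection, and bifurcation-diagram scans.

These operate on any deterministic map ``x -> f(x)`` over scalars or vectors,
including the ODE-composed serial-dilution map from :mod:`feastfamine.model`
and the one-dimensional gLV fraction map from :mod:`feastfamine.glv`.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ConfigError, DiagnosticError
from .model import CRParams

__all__ = [
    "LyapunovResult",
    "BifurcationDiagram",
    "largest_lyapunov",
    "detect_period",
    "bifurcation_scan",
    "interpolate_params",
]

#: floor on trajectory separation: a superstable step contributes a large
#: negative (but finite) log instead of -inf
_SEP_FLOOR = 1e-300


@dataclasses.dataclass(frozen=True)
class LyapunovResult:
    """Largest Lyapunov exponent estimate, in nats per map iteration.

    ``converged`` is True when the running mean drifts less than ``conv_tol``
    over the last quarter of the iterations — a sanity flag, not a guarantee.
    """

    lambda_max: float
    n_transient: int
    n_iter: int
    delta0: float
    converged: bool


def largest_lyapunov(
    map_fn: Callable,
    x0,
    n_transient: int = 200,
    n_iter: int = 1000,
    delta0: float = 1e-8,
    conv_tol: float = 0.05,
) -> LyapunovResult:
    """Benettin two-trajectory estimate of the largest Lyapunov exponent.

    A reference orbit and a companion displaced by ``delta0`` are co-iterated;
    after every step the log of their separation growth is accumulated and the
    companion is pulled back to distance ``delta0`` along the current
    separation direction.  The exponent is the mean accumulated log.

    Parameters
    ----------
    map_fn : callable
        Deterministic map; takes and returns a scalar or 1-D array.
    x0 : float or array-like
        Initial condition (pre-transient).
    delta0 : float
        Initial and renormalised perturbation magnitude, in [1e-12, 1e-4].
    """
    if not (1e-12 <= delta0 <= 1e-4):
        raise ConfigError(f"delta0 must be in [1e-12, 1e-4], got {delta0}")
    if n_iter < 100:
        raise ConfigError(f"n_iter must be >= 100, got {n_iter}")
    scalar = np.isscalar(x0) or np.ndim(x0) == 0
    if scalar:
        return _lyapunov_scalar(map_fn, float(x0), n_transient, n_iter, delta0, conv_tol)
    return _lyapunov_vector(map_fn, np.asarray(x0, dtype=float), n_transient,
                            n_iter, delta0, conv_tol)


def _check_finite(x, label):
    if not np.all(np.isfinite(x)):
        raise DiagnosticError(f"{label} escaped to non-finite values", last_state=x)


def _converged(logs: np.ndarray, conv_tol: float) -> bool:
    running = np.cumsum(logs) / np.arange(1, len(logs) + 1)
    tail = running[-max(len(logs) // 4, 2):]
    return bool(np.ptp(tail) < conv_tol)


def _lyapunov_scalar(map_fn, x, n_transient, n_iter, delta0, conv_tol):
    for _ in range(n_transient):
        x = map_fn(x)
    if not math.isfinite(x):
        raise DiagnosticError("orbit escaped during transient", last_state=x)
    xp = x + delta0
    logs = np.empty(n_iter)
    for k in range(n_iter):
        x = map_fn(x)
        xp = map_fn(xp)
        if not (math.isfinite(x) and math.isfinite(xp)):
            raise DiagnosticError("orbit escaped during iteration", last_state=x)
        sep = abs(xp - x)
        if sep < _SEP_FLOOR:
            sep = _SEP_FLOOR
            xp = x + delta0
        else:
            xp = x + delta0 * (xp - x) / sep
        logs[k] = math.log(sep / delta0)
    lam = float(np.mean(logs))
    return LyapunovResult(lam, n_transient, n_iter, delta0, _converged(logs, conv_tol))


def _lyapunov_vector(map_fn, x, n_transient, n_iter, delta0, conv_tol):
    for _ in range(n_transient):
        x = np.asarray(map_fn(x), dtype=float)
    _check_finite(x, "orbit")
    u = np.ones_like(x) / math.sqrt(x.size)
    xp = x + delta0 * u
    logs = np.empty(n_iter)
    for k in range(n_iter):
        x = np.asarray(map_fn(x), dtype=float)
        xp = np.asarray(map_fn(xp), dtype=float)
        _check_finite(x, "orbit")
        _check_finite(xp, "perturbed orbit")
        diff = xp - x
        sep = float(np.linalg.norm(diff))
        if sep < _SEP_FLOOR:
            sep = _SEP_FLOOR
            xp = x + delta0 * u
        else:
            xp = x + (delta0 / sep) * diff
        logs[k] = math.log(sep / delta0)
    lam = float(np.mean(logs))
    return LyapunovResult(lam, n_transient, n_iter, delta0, _converged(logs, conv_tol))


def detect_period(
    orbit_tail: Sequence[float],
    tol: float = 1e-6,
    max_period: int = 32,
) -> Optional[int]:
    """Smallest period p <= max_period of a post-transient scalar orbit.

    Returns the smallest p such that ``|x[n+p] - x[n]| < tol`` for every n in
    the tail, or ``None`` when the tail is aperiodic at this tolerance.
    Period 1 means a fixed point.
    """
    x = np.asarray(orbit_tail, dtype=float)
    if len(x) < 3 * max_period:
        raise ConfigError(
            f"orbit tail of length {len(x)} too short: need >= 3*max_period = {3 * max_period}"
        )
    for p in range(1, max_period + 1):
        if np.all(np.abs(x[p:] - x[:-p]) < tol):
            return p
    return None


@dataclasses.dataclass
class BifurcationDiagram:
    """Post-transient orbit values along a scan of a bifurcation parameter."""

    scan_values: np.ndarray  #: (m,) strictly increasing grid
    kept_orbits: np.ndarray  #: (m, n_keep) retained iterates per scan value
    lyapunov: Optional[np.ndarray] = None  #: (m,) lambda_max per scan value
    failures: dict = dataclasses.field(default_factory=dict)  #: index -> message

    def to_frame(self, value_name: str = "aux_freq"):
        import pandas as pd

        m, n_keep = self.kept_orbits.shape
        rows = {
            "scan_value": np.repeat(self.scan_values, n_keep),
            "iterate_index": np.tile(np.arange(n_keep), m),
            value_name: self.kept_orbits.ravel(),
        }
        if self.lyapunov is not None:
            rows["lambda_max"] = np.repeat(self.lyapunov, n_keep)
        return pd.DataFrame(rows)


def bifurcation_scan(
    map_factory: Callable[[float], Callable],
    scan_grid: Sequence[float],
    n_transient: int = 200,
    n_keep: int = 100,
    x0=0.5,
    observable: Callable | None = None,
    with_lyapunov: bool = False,
    lyapunov_iter: int = 400,
    delta0: float = 1e-8,
    continuation: bool = False,
) -> BifurcationDiagram:
    """Scan a map family over a parameter grid, keeping post-transient orbits.

    ``map_factory(value)`` builds the map at one grid point; ``observable``
    projects a (possibly vector) state onto the scalar that is recorded
    (default: identity, for scalar maps).  With ``continuation=True`` each
    grid point starts from the previous point's final state instead of
    ``x0`` (hysteresis exploration; off by default so columns of the diagram
    are independent).

    Per-point integration failures are recorded in ``failures`` (NaN rows)
    and the scan continues.
    """
    grid = np.asarray(scan_grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("scan grid must be nonempty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ConfigError("scan grid must be strictly increasing")
    obs = observable if observable is not None else (lambda s: float(np.asarray(s).reshape(())))
    kept = np.full((grid.size, n_keep), np.nan)
    lams = np.full(grid.size, np.nan) if with_lyapunov else None
    failures: dict = {}
    x_start = x0
    for i, val in enumerate(grid):
        fn = map_factory(float(val))
        x = x_start
        try:
            for _ in range(n_transient):
                x = fn(x)
            if not np.all(np.isfinite(x)):
                raise DiagnosticError("orbit escaped during transient", last_state=x)
            for k in range(n_keep):
                x = fn(x)
                if not np.all(np.isfinite(x)):
                    raise DiagnosticError("orbit escaped during iteration", last_state=x)
                kept[i, k] = obs(x)
            if with_lyapunov:
                lams[i] = largest_lyapunov(
                    fn, x, n_transient=0, n_iter=lyapunov_iter, delta0=delta0
                ).lambda_max
        except Exception as err:  # keep scanning; record the failure
            failures[i] = f"{type(err).__name__}: {err}"
            continue
        if continuation:
            x_start = x
    return BifurcationDiagram(scan_values=grid, kept_orbits=kept,
                              lyapunov=lams, failures=failures)


def interpolate_params(theta_stable: CRParams, theta_chaotic: CRParams, s: float) -> CRParams:
    """Linear interpolation between two parameter sets at coordinate s in [0,1].

    Componentwise (1-s)·stable + s·chaotic over every field; s = 0 and s = 1
    return the endpoints exactly.  Used to build bifurcation diagrams along a
    stable-to-chaotic path in parameter space.
    """
    if not 0.0 <= s <= 1.0:
        raise ConfigError(f"s must be in [0, 1], got {s}")
    if s == 0.0:
        return theta_stable
    if s == 1.0:
        return theta_chaotic
    fields = {
        f.name: (1.0 - s) * getattr(theta_stable, f.name) + s * getattr(theta_chaotic, f.name)
        for f in dataclasses.fields(CRParams)
    }
    return CRParams(**fields)
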