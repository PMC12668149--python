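"""Consumer-resource dynamics of a two-strain cross-feeding community under
periodic serial dilution.

The continuous-time model tracks an overproducer ``X1`` and an auxotroph
``X2`` competing for a primary resource ``R1`` (glucose-like), with the
overproducer generating a secondary resource ``R2`` (byproducts plus
necromass) that the auxotroph depends on:

.. math::

    \\dot X_1 &= [\\mu_1 R_1/(K_1+R_1) - d_1]\\, X_1 \\\\
    \\dot X_2 &= [\\mu_{21} R_1/(K_{21}+R_1) + \\mu_{22} R_2/(K_{22}+R_2)
                 - d_2]\\, X_2 \\\\
    \\dot R_1 &= -\\tfrac{1}{Y_1}\\mu_1 \\tfrac{R_1}{K_1+R_1} X_1
                 - \\tfrac{1}{Y_{21}}\\mu_{21} \\tfrac{R_1}{K_{21}+R_1} X_2 \\\\
    \\dot R_2 &= p X_1 + q d_1 X_1
                 - \\tfrac{1}{Y_{22}}\\mu_{22} \\tfrac{R_2}{K_{22}+R_2} X_2

Growth between dilutions follows these ODEs; every ``dt_dilution`` days an
instantaneous transfer keeps a fraction ``D`` of the culture and replenishes
``R1`` with fresh medium at supply concentration ``S``.  The state sampled
immediately after each transfer defines a discrete-time (stroboscopic) map,
the object on which bifurcation diagrams and Lyapunov exponents are computed.

Units: time in days; biomass and resources in arbitrary consistent units
(conversion to CFU/mL lives in :mod:`feastfamine.metrics`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidStateError, ConfigError

__all__ = [
    "CRState",
    "CRParams",
    "SolverConfig",
    "BatchTrajectory",
    "Orbit",
    "STANDARD_STATE0",
    "cr_rhs",
    "integrate_batch",
    "apply_transfer",
    "iterate_map",
    "post_transfer_map",
    "aux_frequency",
    "load_params",
    "save_params",
    "default_params",
    "stable_params",
    "chaotic_params",
    "write_timeseries_csv",
]

#: components more negative than this raise; components in (NEG_CLAMP, 0) are
#: clamped to 0 (solver undershoot protection without masking real bugs)
NEG_CLAMP = -1e-9


class CRState(NamedTuple):
    """Instantaneous community state: two biomasses, two resources."""

    X1: float  #: overproducer biomass
    X2: float  #: auxotroph biomass
    R1: float  #: primary resource (glucose-like)
    R2: float  #: secondary resource (byproducts + necromass)

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CRState":
        if len(y) != 4:
            raise InvalidStateError(f"state needs 4 components, got {len(y)}")
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]))

    def validate(self) -> "CRState":
        for name, v in zip(self._fields, self):
            if not math.isfinite(v):
                raise InvalidStateError(f"non-finite state component {name}={v}")
            if v < NEG_CLAMP:
                raise InvalidStateError(f"negative state component {name}={v}")
        if any(v < 0 for v in self):
            return CRState(*(max(v, 0.0) for v in self))
        return self


def aux_frequency(state: CRState) -> float:
    """Auxotroph relative frequency X2/(X1+X2); 0 for an empty community."""
    total = state.X1 + state.X2
    return state.X2 / total if total > 0 else 0.0


# Fields optimisable by the calibration pipeline (everything kinetic; the
# operating conditions D, S, dt_dilution are experimental design, not biology).
KINETIC_FIELDS = (
    "mu1", "K1", "mu21", "K21", "mu22", "K22",
    "Y1", "Y21", "Y22", "p", "q", "d1", "d2",
)


@dataclasses.dataclass(frozen=True)
class CRParams:
    """Kinetic constants and operating conditions of the serial-dilution model.

    Parameters
    ----------
    mu1, K1 : float
        Max specific growth rate (1/day) and half-saturation of the
        overproducer on R1.
    mu21, K21 : float
        Same for the auxotroph's growth on the primary resource.
    mu22, K22 : float
        Same for the auxotroph's growth on the secondary resource.
    Y1, Y21, Y22 : float
        Yield coefficients (biomass produced per resource consumed) for the
        three uptake channels above.
    p : float
        R2 secretion rate per unit of live overproducer biomass (1/day on
        the resource scale).
    q : float
        Fraction of dead overproducer biomass recycled into R2 (necromass
        channel), dimensionless in [0, 1].
    d1, d2 : float
        Per-capita death rates (1/day).
    D : float
        Dilution survival fraction at transfer (1:10 bottleneck -> 0.1).
    S : float
        Fresh-medium concentration of R1.
    dt_dilution : float
        Dilution interval Δt in days.
    """

    mu1: float
    K1: float
    mu21: float
    K21: float
    mu22: float
    K22: float
    Y1: float
    Y21: float
    Y22: float
    p: float
    q: float
    d1: float
    d2: float
    D: float = 0.1
    S: float = 10.0
    dt_dilution: float = 10.0

    def __post_init__(self):
        for name in KINETIC_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigError(f"CRParams.{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.q <= 1.0:
            raise ConfigError(f"CRParams.q must be in [0, 1], got {self.q}")
        if not 0.0 < self.D < 1.0:
            raise ConfigError(f"CRParams.D must be in (0, 1), got {self.D}")
        if not self.S >= 0:
            raise ConfigError(f"CRParams.S must be >= 0, got {self.S}")
        if not self.dt_dilution > 0:
            raise ConfigError(f"CRParams.dt_dilution must be > 0, got {self.dt_dilution}")

    def replace(self, **changes) -> "CRParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CRParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown CRParams keys: {sorted(unknown)}")
        missing = {f.name for f in dataclasses.fields(cls) if f.default is dataclasses.MISSING} - set(d)
        if missing:
            raise ConfigError(f"missing CRParams keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})


def load_params(path) -> CRParams:
    """Load a flat-JSON parameter set; unknown keys are rejected."""
    with open(path) as fh:
        return CRParams.from_dict(json.load(fh))


def save_params(params: CRParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _data_path(name: str):
    import importlib.resources as res

    return res.files("feastfamine.data").joinpath(name)


def default_params() -> CRParams:
    """The shipped calibrated parameter set (reference for all regime claims)."""
    with _data_path("default_cr_params.json").open() as fh:
        return CRParams.from_dict(json.load(fh))


def stable_params() -> CRParams:
    """A parameter set with stable, convergent post-transfer dynamics."""
    with _data_path("cr_stable_params.json").open() as fh:
        return CRParams.from_dict(json.load(fh))


def chaotic_params() -> CRParams:
    """A parameter set with chaotic post-transfer dynamics (λ > 0)."""
    with _data_path("cr_chaotic_params.json").open() as fh:
        return CRParams.from_dict(json.load(fh))


#: standard initial condition for map/attractor analyses: equal small
#: inocula into fresh medium
STANDARD_STATE0 = CRState(X1=0.05, X2=0.05, R1=10.0, R2=0.0)


def cr_rhs(state: CRState, params: CRParams) -> tuple:
    """Time derivative (dX1, dX2, dR1, dR2) of the consumer-resource system.

    Monod uptake throughout; the auxotroph's two carbon channels (R1, R2)
    contribute additively to its growth.  R2 is sourced by secretion from
    live overproducers (p·X1) and by recycling of dead ones (q·d1·X1).
    R1 is never produced, so dR1 <= 0 always.
    """
    s = CRState(*state)
    for name, v in zip(s._fields, s):
        if not math.isfinite(v):
            raise InvalidStateError(f"non-finite state component {name}={v}")
    return _rhs(0.0, s.as_array(), params)


def _rhs(t, y, p: CRParams):
    X1, X2, R1, R2 = y
    # clip to guard Monod terms against adaptive-solver undershoot
    X1c = X1 if X1 > 0.0 else 0.0
    X2c = X2 if X2 > 0.0 else 0.0
    R1c = R1 if R1 > 0.0 else 0.0
    R2c = R2 if R2 > 0.0 else 0.0
    f1 = p.mu1 * R1c / (p.K1 + R1c) if R1c > 0 else 0.0
    f21 = p.mu21 * R1c / (p.K21 + R1c) if R1c > 0 else 0.0
    f22 = p.mu22 * R2c / (p.K22 + R2c) if R2c > 0 else 0.0
    dX1 = (f1 - p.d1) * X1c
    dX2 = (f21 + f22 - p.d2) * X2c
    dR1 = -(f1 / p.Y1) * X1c - (f21 / p.Y21) * X2c
    dR2 = p.p * X1c + p.q * p.d1 * X1c - (f22 / p.Y22) * X2c
    return (dX1, dX2, dR1, dR2)


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    """Adaptive-integrator settings for batch (between-dilution) dynamics.

    LSODA switches between nonstiff and stiff methods, which suits the fast
    resource-depletion transient followed by a long famine phase.
    """

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    #: solutions may undershoot 0 by ~rtol·(state scale); components in
    #: (neg_clamp, 0) are set to 0, anything more negative raises
    neg_clamp: float = -1e-6


DEFAULT_SOLVER = SolverConfig()


@dataclasses.dataclass
class BatchTrajectory:
    """Sampled solution of one batch (between consecutive dilutions)."""

    times: np.ndarray  #: (n,) strictly increasing, times[0] == 0
    states: np.ndarray  #: (n, 4) columns X1, X2, R1, R2

    @property
    def final_state(self) -> CRState:
        return CRState.from_array(self.states[-1])

    @property
    def X1(self):
        return self.states[:, 0]

    @property
    def X2(self):
        return self.states[:, 1]

    @property
    def R1(self):
        return self.states[:, 2]

    @property
    def R2(self):
        return self.states[:, 3]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_or_cycle": self.times,
                "X1": self.X1,
                "X2": self.X2,
                "R1": self.R1,
                "R2": self.R2,
                "aux_freq": [aux_frequency(CRState.from_array(s)) for s in self.states],
            }
        )


def _clamp_column(y: np.ndarray, t: np.ndarray, threshold: float = -1e-6) -> np.ndarray:
    """Apply the negative-clamping rule to solver output."""
    bad = y < threshold
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise IntegrationError(
            f"state component {CRState._fields[int(i)]} = {y[i, j]:.3e} "
            f"below clamp threshold at t = {t[j]:.6g}",
            last_valid_time=float(t[j - 1]) if j > 0 else 0.0,
        )
    return np.where(y < 0.0, 0.0, y)


def integrate_batch(
    state0: CRState,
    params: CRParams,
    duration: float,
    solver: SolverConfig | None = None,
    n_points: int = 201,
    t_eval: Sequence[float] | None = None,
) -> BatchTrajectory:
    """Integrate one batch of growth for ``duration`` days (no dilution).

    Returns a trajectory sampled at ``t_eval`` (default: ``n_points`` evenly
    spaced times including 0 and ``duration``).
    """
    if not duration > 0:
        raise ConfigError(f"duration must be > 0, got {duration}")
    solver = solver or DEFAULT_SOLVER
    s0 = CRState(*state0).validate()
    if t_eval is None:
        t_eval = np.linspace(0.0, duration, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval[0] != 0.0 or t_eval[-1] != duration:
            raise ConfigError("t_eval must start at 0 and end at duration")
    sol = solve_ivp(
        _rhs,
        (0.0, duration),
        s0.as_array(),
        args=(params,),
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        t_eval=t_eval,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"solver failed: {sol.message}", last_valid_time=last)
    y = _clamp_column(sol.y, sol.t, solver.neg_clamp)
    # extinction is an invariant manifold of the flow: a species starting at
    # exactly 0 stays 0 (solver round-off would otherwise seed phantom growth)
    for i in (0, 1):
        if s0[i] == 0.0:
            y[i, :] = 0.0
    if not np.isfinite(y).all():
        raise IntegrationError("non-finite state in solution", last_valid_time=float(sol.t[0]))
    return BatchTrajectory(times=sol.t.copy(), states=y.T.copy())


def _terminal_state(state0: CRState, params: CRParams, duration: float,
                    solver: SolverConfig) -> CRState:
    """Endpoint-only batch integration (no intermediate sampling)."""
    sol = solve_ivp(
        _rhs,
        (0.0, duration),
        state0.as_array(),
        args=(params,),
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        t_eval=(duration,),
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"solver failed: {sol.message}", last_valid_time=last)
    y = _clamp_column(sol.y, sol.t, solver.neg_clamp)[:, -1]
    for i in (0, 1):  # extinct species stay extinct (invariant manifold)
        if state0[i] == 0.0:
            y[i] = 0.0
    if not np.isfinite(y).all():
        raise IntegrationError("non-finite terminal state", last_valid_time=duration)
    return CRState.from_array(y)


def apply_transfer(state: CRState, params: CRParams) -> CRState:
    """Instantaneous 1:(1/D) dilution into fresh medium.

    A fraction D of everything in the old culture carries over (biomass,
    leftover R1, and accumulated byproducts/necromass R2); fresh medium
    contributes (1-D)·S of R1 and no R2.
    """
    s = CRState(*state).validate()
    d = params.D
    return CRState(
        X1=d * s.X1,
        X2=d * s.X2,
        R1=d * s.R1 + (1.0 - d) * params.S,
        R2=d * s.R2,
    )


@dataclasses.dataclass
class Orbit:
    """Post-transfer states of the discrete serial-dilution map."""

    cycle_index: np.ndarray  #: (n,) 1-based transfer counter
    states: np.ndarray  #: (n, 4) state immediately after each transfer
    aux_freq: np.ndarray  #: (n,) auxotroph relative frequency per entry

    def __len__(self):
        return len(self.cycle_index)

    def post_transfer_states(self):
        return [CRState.from_array(s) for s in self.states]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_or_cycle": self.cycle_index,
                "X1": self.states[:, 0],
                "X2": self.states[:, 1],
                "R1": self.states[:, 2],
                "R2": self.states[:, 3],
                "aux_freq": self.aux_freq,
            }
        )


def iterate_map(
    state0: CRState,
    params: CRParams,
    n_cycles: int,
    solver: SolverConfig | None = None,
) -> Orbit:
    """Iterate the serial-dilution map: integrate Δt days, transfer, repeat.

    Entry ``k`` (1-based) is the state immediately after the k-th transfer.
    Deterministic given (state0, params, solver).
    """
    if n_cycles < 1:
        raise ConfigError(f"n_cycles must be >= 1, got {n_cycles}")
    solver = solver or DEFAULT_SOLVER
    s = CRState(*state0).validate()
    states = np.empty((n_cycles, 4))
    freqs = np.empty(n_cycles)
    for k in range(n_cycles):
        try:
            end = _terminal_state(s, params, params.dt_dilution, solver)
        except IntegrationError as err:
            err.cycle_index = k + 1
            raise
        s = apply_transfer(end, params)
        states[k] = s.as_array()
        freqs[k] = aux_frequency(s)
    return Orbit(cycle_index=np.arange(1, n_cycles + 1), states=states, aux_freq=freqs)


def post_transfer_map(
    params: CRParams, solver: SolverConfig | None = None
) -> Callable[[np.ndarray], np.ndarray]:
    """The serial-dilution map as a plain function on 4-vectors.

    Maps a post-transfer state to the next post-transfer state; the form
    consumed by :mod:`feastfamine.chaos`.
    """
    solver = solver or DEFAULT_SOLVER

    def _map(y: np.ndarray) -> np.ndarray:
        s = CRState.from_array(np.asarray(y, dtype=float)).validate()
        end = _terminal_state(s, params, params.dt_dilution, solver)
        return apply_transfer(end, params).as_array()

    return _map


def write_timeseries_csv(path, frame) -> None:
    """Write a trajectory/orbit frame with full double precision."""
    cols = ["time_or_cycle", "X1", "X2", "R1", "R2", "aux_freq"]
    frame.to_csv(path, index=False, columns=cols, float_format="%.17g")
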