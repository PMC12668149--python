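"""Nested four-stage calibration of the consumer-resource model.

The fitting procedure mirrors how such co-culture models are calibrated in
practice: each stage fixes what the previous stage learned and frees only
the parameters its data can inform.

1. ``fit_monoculture`` — overproducer kinetics (mu1, K1, Y1, d1) against a
   monoculture growth curve.
2. ``fit_auxotroph`` — auxotroph-specific parameters against co-culture
   trajectories, with the cross-competition channel forced off (mu21 = 0).
3. ``fit_global`` — competition parameters introduced and a seeded global
   (differential evolution) search plus local polish over the full
   identifiable kinetic set, bounded around the prior stage's values.
4. ``calibrate_dilution`` — a seeded uniform sample in a bounded box around
   the fitted parameters, scored by squared error of per-cycle auxotroph
   relative frequencies under the serial-dilution map, with local polish.

Biomass-trajectory stages use a log-scale sum of squared errors (CFU span
several decades); the dilution stage uses squared frequency error.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares, minimize

from .errors import (ConfigError, DataError, FeastFamineError, FitError,
                     IntegrationError, InvalidStateError)
from .model import (
    CRParams,
    CRState,
    KINETIC_FIELDS,
    SolverConfig,
    integrate_batch,
    iterate_map,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ObservationMapping",
    "loss_log_sse",
    "residuals_log",
    "abundance_sse",
    "residuals_abundance",
    "fit_monoculture",
    "fit_auxotroph",
    "fit_global",
    "calibrate_dilution",
    "run_pipeline",
]

#: sentinel loss for parameter vectors whose simulation fails; finite so
#: population-based optimizers can continue past them
PENALTY_LOSS = 1e12

_STAGES = ("monoculture", "auxotroph", "global", "dilution")

_STAGE_DEFAULT_FREE = {
    "monoculture": ("mu1", "K1", "Y1", "d1"),
    # p and q source R2 as (p + q·d1)·X1: only the combination is
    # identifiable from trajectories, so q stays fixed by default
    "auxotroph": ("mu22", "K22", "Y22", "d2", "p"),
    "global": ("mu1", "K1", "mu21", "K21", "mu22", "K22", "Y1", "Y21", "Y22", "p", "d1", "d2"),
    "dilution": ("mu1", "K1", "mu21", "K21", "mu22", "K22", "Y1", "Y21", "Y22", "p", "d1", "d2"),
}

#: default solver for calibration simulations: slightly looser than the
#: analysis default, for speed inside optimizer loops
FIT_SOLVER = SolverConfig(method="LSODA", rtol=1e-7, atol=1e-9, neg_clamp=-1e-5)


@dataclasses.dataclass(frozen=True)
class ObservationMapping:
    """How observed values map onto model state.

    ``cfu_per_biomass`` converts model biomass to CFU/mL;
    ``od_per_biomass`` converts to OD600.  ``state0`` is the batch initial
    condition used when simulating the observed experiment.
    """

    state0: CRState
    cfu_per_biomass: float = 1e8
    od_per_biomass: float = 1.0

    def scale(self, value_type: str) -> float:
        if value_type == "CFU_per_mL":
            return self.cfu_per_biomass
        if value_type == "OD600":
            return self.od_per_biomass
        raise DataError(f"unknown value_type {value_type!r}")


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Configuration of one calibration stage."""

    stage: str
    free_params: tuple = ()
    bounds: Mapping[str, tuple] = dataclasses.field(default_factory=dict)
    loss: str = "log_sse"
    seed: int = 1
    n_samples: int = 200          # dilution stage only
    max_evals: int = 5000
    box_width: float = 0.5        # ±50% multiplicative box (global/dilution)
    #: kinetic constants known a priori (measured or by convention), applied
    #: to the stage's base parameters and never optimised
    fixed_values: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ConfigError(f"stage must be one of {_STAGES}, got {self.stage!r}")
        free = tuple(self.free_params) or _STAGE_DEFAULT_FREE[self.stage]
        bad = set(free) - set(KINETIC_FIELDS)
        if bad:
            raise ConfigError(f"free_params not kinetic CRParams fields: {sorted(bad)}")
        object.__setattr__(self, "free_params", free)
        bad_fixed = set(self.fixed_values) - set(KINETIC_FIELDS)
        if bad_fixed:
            raise ConfigError(f"fixed_values not kinetic CRParams fields: {sorted(bad_fixed)}")
        overlap = set(self.fixed_values) & set(free)
        if overlap:
            raise ConfigError(f"fields both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in dict(self.bounds).items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ConfigError(f"invalid bounds for {name}: ({lo}, {hi})")
        if self.loss not in ("log_sse", "abundance_sse"):
            raise ConfigError(f"unknown loss {self.loss!r}")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.max_evals < 1:
            raise ConfigError("max_evals must be >= 1")


@dataclasses.dataclass
class FitResult:
    """Outcome of one calibration stage."""

    params: CRParams
    loss_value: float
    stage: str
    fixed_from_prior: tuple
    trace: list  #: (eval_index, best-so-far loss) history
    diagnostics: dict = dataclasses.field(default_factory=dict)


def _check_observed(observed: pd.DataFrame) -> pd.DataFrame:
    needed = {"time_days", "species", "value", "value_type"}
    missing = needed - set(observed.columns)
    if missing:
        raise DataError(f"observed data missing columns: {sorted(missing)}")
    if (observed["value"] <= 0).any():
        raise DataError("observed values must be positive (impute zeros first)")
    return observed


def residuals_log(
    observed: pd.DataFrame,
    params: CRParams,
    mapping: ObservationMapping,
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """Per-observation log residuals ln(obs) − ln(sim), one batch simulation.

    Simulation failures raise; use :func:`loss_log_sse` for the penalised
    scalar objective.
    """
    _check_observed(observed)
    solver = solver or FIT_SOLVER
    times = np.unique(observed["time_days"].to_numpy(dtype=float))
    if times[0] < 0:
        raise DataError("negative observation times")
    t_eval = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    duration = float(times[-1])
    traj = integrate_batch(mapping.state0, params, duration, solver=solver, t_eval=t_eval)
    sim_col = {"overproducer": traj.X1, "auxotroph": traj.X2}
    t_index = {t: i for i, t in enumerate(traj.times)}
    out = np.empty(len(observed))
    for i, row in enumerate(observed.itertuples(index=False)):
        sim = sim_col[row.species][t_index[float(row.time_days)]]
        sim_obs_scale = sim * mapping.scale(row.value_type)
        if sim_obs_scale <= 0:
            out[i] = 50.0  # ~e^50-fold mismatch: finite but hopeless
        else:
            out[i] = math.log(row.value) - math.log(sim_obs_scale)
    return out


def loss_log_sse(
    observed: pd.DataFrame,
    params: CRParams,
    mapping: ObservationMapping,
    solver: SolverConfig | None = None,
) -> float:
    """Σ (ln observed − ln simulated)² over species and time points.

    Simulates one batch from ``mapping.state0`` spanning the observation
    times.  Simulation failures return :data:`PENALTY_LOSS` rather than
    raising, so optimizers can continue.
    """
    _check_observed(observed)
    try:
        r = residuals_log(observed, params, mapping, solver)
    except (IntegrationError, InvalidStateError):
        return PENALTY_LOSS
    return float(np.sum(r ** 2))


def residuals_abundance(
    dilution_data: pd.DataFrame,
    params: CRParams,
    state0: CRState,
    solver: SolverConfig | None = None,
) -> np.ndarray:
    """Per-cycle residuals observed − simulated post-transfer aux_freq."""
    if not {"cycle", "aux_freq"} <= set(dilution_data.columns):
        raise DataError("dilution data needs columns cycle, aux_freq")
    cycles = dilution_data["cycle"].to_numpy(dtype=int)
    if (cycles < 1).any():
        raise DataError("cycle indices must be >= 1")
    n_cycles = int(cycles.max())
    orbit = iterate_map(state0, params, n_cycles, solver=solver or FIT_SOLVER)
    obs = dilution_data["aux_freq"].to_numpy(dtype=float)
    return obs - orbit.aux_freq[cycles - 1]


def abundance_sse(
    dilution_data: pd.DataFrame,
    params: CRParams,
    state0: CRState,
    solver: SolverConfig | None = None,
) -> float:
    """Σ over cycles of (observed aux_freq − simulated post-transfer aux_freq)²."""
    try:
        r = residuals_abundance(dilution_data, params, state0, solver)
    except (IntegrationError, InvalidStateError):
        return PENALTY_LOSS
    return float(np.sum(r ** 2))


def _default_bounds(value: float, width: float = 0.5, floor: float = 1e-8) -> tuple:
    lo = max(value * (1.0 - width), 0.0)
    hi = value * (1.0 + width)
    if hi <= lo + floor:  # parameter at/near zero: open a small absolute box
        lo, hi = 0.0, max(10 * floor, value * 2, 0.1)
    return (lo, hi)


#: wide absolute search boxes for the data-poor early stages (no usable prior)
_ABS_BOUNDS = {
    "mu1": (0.1, 30.0), "K1": (0.01, 10.0), "Y1": (0.01, 10.0), "d1": (1e-3, 5.0),
    "mu21": (0.0, 30.0), "K21": (0.01, 10.0), "Y21": (0.01, 10.0),
    "mu22": (0.1, 30.0), "K22": (0.01, 10.0), "Y22": (0.01, 10.0), "d2": (1e-3, 5.0),
    "p": (0.0, 2.0), "q": (0.0, 1.0),
}


def _resolve_bounds(config: FitConfig, prior: CRParams) -> list:
    out = []
    for name in config.free_params:
        if name in config.bounds:
            out.append(tuple(config.bounds[name]))
        elif config.stage in ("monoculture", "auxotroph"):
            out.append(_ABS_BOUNDS[name])
        else:
            out.append(_default_bounds(getattr(prior, name), config.box_width))
    return out


class _Objective:
    """Penalised objective over the free-parameter subvector, with trace."""

    def __init__(self, config: FitConfig, base: CRParams, loss_fn,
                 residual_fn=None):
        self.config = config
        self.base = base
        self.loss_fn = loss_fn
        self.residual_fn = residual_fn
        self.n_evals = 0
        self.trace: list = []
        self.best = math.inf

    def params_at(self, x: np.ndarray) -> CRParams:
        updates = dict(zip(self.config.free_params, (float(v) for v in x)))
        if "q" in updates:
            updates["q"] = min(max(updates["q"], 0.0), 1.0)
        return self.base.replace(**{k: max(v, 0.0) for k, v in updates.items()})

    def __call__(self, x: np.ndarray) -> float:
        self.n_evals += 1
        try:
            val = self.loss_fn(self.params_at(x))
        except FeastFamineError:
            val = PENALTY_LOSS
        if not math.isfinite(val):
            val = PENALTY_LOSS
        if val < self.best:
            self.best = val
            self.trace.append((self.n_evals, val))
        return val


def _polish(obj: _Objective, x0: np.ndarray, bounds: list, max_evals: int) -> np.ndarray:
    """Local polish: Gauss-Newton on residuals when available, else Nelder-Mead."""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    if obj.residual_fn is not None:
        def resid(x):
            obj.n_evals += 1
            try:
                return obj.residual_fn(obj.params_at(np.clip(x, lo, hi)))
            except FeastFamineError:
                return np.full(1, 1e6)

        try:
            n_res = len(resid(x0))

            def resid_fixed(x):
                r = resid(x)
                return r if len(r) == n_res else np.full(n_res, 1e6)

            sol = least_squares(
                resid_fixed, np.clip(x0, lo, hi), bounds=(lo, hi),
                max_nfev=max(max_evals // (len(bounds) + 1), 2),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            return np.clip(sol.x, lo, hi)
        except Exception:
            pass  # fall through to derivative-free polish

    def clipped(x):
        return obj(np.clip(x, lo, hi))

    res = minimize(clipped, x0, method="Nelder-Mead",
                   options={"maxfev": max_evals, "xatol": 1e-10, "fatol": 1e-12})
    return np.clip(res.x, lo, hi)


def _run_stage(config: FitConfig, base: CRParams, loss_fn, fixed: tuple,
               global_search: bool, residual_fn=None) -> FitResult:
    obj = _Objective(config, base, loss_fn, residual_fn)
    bounds = _resolve_bounds(config, base)
    x_prior = np.array([getattr(base, n) for n in config.free_params], dtype=float)
    x_prior = np.clip(x_prior, [b[0] for b in bounds], [b[1] for b in bounds])
    loss_prior = obj(x_prior)

    budget = config.max_evals
    x_best, loss_best = x_prior, loss_prior
    if global_search and budget > 20 * len(bounds):
        popsize = 15
        maxiter = max((budget // 2) // (popsize * len(bounds)) - 1, 1)
        de = differential_evolution(
            obj, bounds, seed=config.seed, maxiter=maxiter, popsize=popsize,
            init="sobol", tol=1e-10, polish=False, updating="deferred",
        )
        if de.fun < loss_best:
            x_best, loss_best = np.asarray(de.x), float(de.fun)
    remaining = max(budget - obj.n_evals, 0)
    if remaining > 2 * len(bounds):
        x_pol = _polish(obj, x_best, bounds, remaining)
        loss_pol = obj(x_pol)
        if loss_pol < loss_best:
            x_best, loss_best = x_pol, loss_pol

    if loss_best >= PENALTY_LOSS:
        raise FitError(f"{config.stage} stage: every evaluation penalised",
                       trace=obj.trace, initial_guess=x_prior.tolist())
    params = obj.params_at(x_best)
    return FitResult(params=params, loss_value=float(loss_best), stage=config.stage,
                     fixed_from_prior=fixed, trace=obj.trace,
                     diagnostics={"n_evals": obj.n_evals})


def fit_monoculture(
    growth_data: pd.DataFrame,
    config: FitConfig,
    mapping: ObservationMapping,
) -> FitResult:
    """Stage 1: overproducer kinetics from monoculture growth data.

    ``growth_data`` must contain only overproducer observations.  A flat
    series (no dynamic information) is flagged non-identifiable in
    ``diagnostics`` rather than fitted silently.
    """
    _check_observed(growth_data)
    if set(growth_data["species"].unique()) != {"overproducer"}:
        raise DataError("monoculture stage expects overproducer-only data")
    allowed = {"mu1", "K1", "Y1", "d1"}
    if not set(config.free_params) <= allowed:
        raise ConfigError(f"monoculture free_params must be within {sorted(allowed)}")
    # start from a neutral guess: unit kinetics at the data's scale
    base = CRParams(
        mu1=1.0, K1=1.0, mu21=0.0, K21=1.0, mu22=0.0, K22=1.0,
        Y1=1.0, Y21=1.0, Y22=1.0, p=0.0, q=0.0, d1=0.1, d2=0.0,
        D=0.1, S=float(mapping.state0.R1), dt_dilution=1.0,
    ).replace(**dict(config.fixed_values))
    values = growth_data["value"].to_numpy(dtype=float)
    rel_range = float(values.max() / values.min()) - 1.0
    result = _run_stage(
        config, base,
        lambda p: loss_log_sse(growth_data, p, mapping),
        fixed=(), global_search=True,
        residual_fn=lambda p: residuals_log(growth_data, p, mapping),
    )
    if rel_range < 1e-3:
        result.diagnostics["non_identifiable"] = True
        result.diagnostics["reason"] = "flat series: no dynamic information"
    return result


def _require_stage(prior: FitResult, expected: str) -> None:
    if prior.stage != expected:
        raise ConfigError(f"prior must come from the {expected!r} stage, got {prior.stage!r}")


def fit_auxotroph(
    coculture_data: pd.DataFrame,
    prior: FitResult,
    config: FitConfig,
    mapping: ObservationMapping,
) -> FitResult:
    """Stage 2: auxotroph parameters from co-culture, no R1 competition.

    Overproducer parameters are carried over bit-identically from the
    monoculture stage; mu21 is forced to 0 (the auxotroph is assumed not to
    compete for the primary resource at this stage).
    """
    _require_stage(prior, "monoculture")
    allowed = {"mu22", "K22", "Y22", "d2", "p", "q"}
    if not set(config.free_params) <= allowed:
        raise ConfigError(f"auxotroph free_params must be within {sorted(allowed)}")
    base = prior.params.replace(mu21=0.0, mu22=1.0, K22=1.0, Y22=1.0, d2=0.1)
    base = base.replace(**dict(config.fixed_values))
    fixed = ("mu1", "K1", "Y1", "d1")
    result = _run_stage(
        config, base,
        lambda p: loss_log_sse(coculture_data, p, mapping),
        fixed=fixed, global_search=True,
        residual_fn=lambda p: residuals_log(coculture_data, p, mapping),
    )
    for name in fixed:
        if getattr(result.params, name) != getattr(prior.params, name):
            raise FitError(f"prior parameter {name} was modified by the auxotroph stage")
    if result.params.mu21 != 0.0:
        raise FitError("mu21 must remain 0 in the auxotroph stage")
    return result


def fit_global(
    coculture_data: pd.DataFrame,
    prior: FitResult,
    config: FitConfig,
    mapping: ObservationMapping,
) -> FitResult:
    """Stage 3: introduce competition and globally optimise the kinetic set.

    Seeded differential evolution within bounds centred on the prior values,
    followed by derivative-free polish; the returned loss never exceeds the
    prior parameters' loss on this stage's objective.
    """
    _require_stage(prior, "auxotroph")
    base = prior.params.replace(**dict(config.fixed_values))
    if "mu21" in config.free_params and "mu21" not in config.bounds:
        # prior mu21 is pinned at 0; open an absolute box against mu1
        config = dataclasses.replace(
            config, bounds={**dict(config.bounds), "mu21": (0.0, base.mu1),
                            "K21": (1e-3, 10.0 * max(base.K1, 0.1))},
        )
    result = _run_stage(
        config, base,
        lambda p: loss_log_sse(coculture_data, p, mapping),
        fixed=(), global_search=True,
        residual_fn=lambda p: residuals_log(coculture_data, p, mapping),
    )
    prior_loss = loss_log_sse(coculture_data, base, mapping)
    if result.loss_value > prior_loss:
        result = FitResult(params=base, loss_value=prior_loss, stage="global",
                           fixed_from_prior=(), trace=result.trace,
                           diagnostics=result.diagnostics)
    result.stage = "global"
    return result


def calibrate_dilution(
    dilution_data: pd.DataFrame,
    prior: FitResult,
    config: FitConfig,
    state0: CRState,
    dt_dilution: float | None = None,
) -> FitResult:
    """Stage 4: match per-cycle relative abundances across serial dilutions.

    Draws ``config.n_samples`` parameter vectors uniformly (seeded) from the
    multiplicative box of width ``config.box_width`` around the prior
    parameters (the prior itself is always sample 0), scores each by
    :func:`abundance_sse`, and polishes the argmin locally.

    ``dt_dilution`` is the dilution interval of the experiment that produced
    ``dilution_data`` (defaults to the prior parameters' value).
    """
    _require_stage(prior, "global")
    base = prior.params.replace(**dict(config.fixed_values))
    if dt_dilution is not None:
        base = base.replace(dt_dilution=float(dt_dilution))
    obj = _Objective(config, base,
                     lambda p: abundance_sse(dilution_data, p, state0),
                     residual_fn=lambda p: residuals_abundance(dilution_data, p, state0))
    bounds = _resolve_bounds(config, base)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x_prior = np.clip(np.array([getattr(base, n) for n in config.free_params]), lo, hi)

    rng = np.random.default_rng(config.seed)
    best_x, best_loss = x_prior, obj(x_prior)
    for _ in range(config.n_samples - 1):
        x = rng.uniform(lo, hi)
        val = obj(x)
        if val < best_loss:
            best_x, best_loss = x, val
    remaining = max(config.max_evals - obj.n_evals, 0)
    if remaining > 2 * len(bounds) and best_loss > 0:
        x_pol = _polish(obj, best_x, bounds, remaining)
        val = obj(x_pol)
        if val < best_loss:
            best_x, best_loss = x_pol, val
    if best_loss >= PENALTY_LOSS:
        raise FitError("dilution stage: every evaluation penalised", trace=obj.trace)
    return FitResult(params=obj.params_at(best_x), loss_value=float(best_loss),
                     stage="dilution", fixed_from_prior=(), trace=obj.trace,
                     diagnostics={"n_evals": obj.n_evals})


def run_pipeline(
    growth_data: pd.DataFrame,
    coculture_data: pd.DataFrame,
    dilution_data: pd.DataFrame,
    mapping: ObservationMapping,
    dilution_state0: CRState,
    seed: int = 1,
    max_evals: int = 5000,
    n_samples: int = 200,
    dt_dilution: float | None = None,
    free_overrides: Mapping[str, Sequence[str]] | None = None,
    fixed_values: Mapping[str, float] | None = None,
) -> dict:
    """All four stages in sequence; returns {stage: FitResult}."""
    over = {k: tuple(v) for k, v in (free_overrides or {}).items()}
    fixed = dict(fixed_values or {})

    def cfg(stage, **kw):
        return FitConfig(stage=stage, free_params=over.get(stage, ()),
                         seed=seed, max_evals=max_evals, fixed_values=fixed, **kw)

    r1 = fit_monoculture(growth_data, cfg("monoculture"), mapping)
    r2 = fit_auxotroph(coculture_data, r1, cfg("auxotroph"), mapping)
    r3 = fit_global(coculture_data, r2, cfg("global"), mapping)
    r4 = calibrate_dilution(dilution_data, r3, cfg("dilution", n_samples=n_samples),
                            dilution_state0, dt_dilution=dt_dilution)
    return {"monoculture": r1, "auxotroph": r2, "global": r3, "dilution": r4}
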