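"""Synthetic observational data with known ground truth.

Generates the three kinds of input the calibration and metrics modules
consume — plate-reader growth curves, co-culture CFU time series, and
serial-dilution frequency series with spot-plate count tables — from the
consumer-resource model (or a plain logistic curve), so that every pipeline
stage is testable without laboratory data.

All randomness is driven by a single integer seed per artifact; independent
streams are split by a fixed per-output counter so adding an output never
perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .metrics import GrowthFit, logistic_curve
from .model import CRParams, CRState, SolverConfig, integrate_batch, iterate_map

__all__ = [
    "NoiseModel",
    "CFU_PER_BIOMASS",
    "OD_FLOOR",
    "COUNTABLE_RANGE",
    "gen_growth_curve",
    "gen_coculture_series",
    "gen_dilution_series",
    "coculture_qualitative_ok",
    "DEFAULT_COCULTURE_STATE0",
    "write_artifact_csv",
    "recovery_theta",
    "gen_recovery_dataset",
    "RECOVERY_FIXED",
    "RECOVERY_FREE",
    "RECOVERY_DILUTION_DT",
]

#: fixed conversion between model biomass units and CFU/mL (recorded in
#: artifact metadata; arbitrary but consistent across the package)
CFU_PER_BIOMASS = 1e8

#: optical-density readings are floored here (plate-reader blank level)
OD_FLOOR = 1e-4

#: colonies per spot considered countable in synthetic plating
COUNTABLE_RANGE = (3.0, 300.0)

#: available ten-fold serial dilution ladder for synthetic spot plating
_DILUTION_LADDER = tuple(10.0 ** k for k in range(0, 9))

_DEFAULT_PLATED_UL = 5.0


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for synthetic artifacts.

    od_sigma: additive Gaussian s.d. on OD readings (OD units).
    cfu_sigma_log: s.d. of multiplicative lognormal noise on CFU values
    (natural-log units).  Both may be zero for noiseless self-consistency
    checks.
    """

    od_sigma: float = 0.005
    cfu_sigma_log: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.od_sigma < 0 or self.cfu_sigma_log < 0:
            raise ConfigError("noise sigmas must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one artifact stream (counter-split)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


# fixed stream counters, one per generator
_STREAM_GROWTH = 0
_STREAM_COCULTURE = 1
_STREAM_DILUTION = 2


def gen_growth_curve(
    truth: GrowthFit,
    times: Sequence[float],
    noise: NoiseModel | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Logistic OD600 growth curve plus additive Gaussian noise.

    Emulates a plate-reader series (e.g. 15-minute readings over 20 hours).
    Returns (frame with columns time, od; metadata embedding ground truth
    and seed).
    """
    noise = noise or NoiseModel()
    t = np.asarray(times, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ConfigError("times must be increasing with >= 2 points")
    od = logistic_curve(t, truth.K, truth.r, truth.N0)
    if noise.od_sigma > 0:
        od = od + noise.rng(_STREAM_GROWTH).normal(0.0, noise.od_sigma, size=od.shape)
    od = np.maximum(od, OD_FLOOR)
    frame = pd.DataFrame({"time": t, "od": od})
    meta = {
        "truth": {"K": truth.K, "r": truth.r, "N0": truth.N0},
        "od_sigma": noise.od_sigma,
        "seed": noise.seed,
    }
    return frame, meta


#: default co-culture inoculum: overproducer-majority (9:1 by biomass),
#: emulating the early viable-cell composition of a freshly assembled
#: overproducer/auxotroph co-culture
DEFAULT_COCULTURE_STATE0 = CRState(X1=0.09, X2=0.01, R1=10.0, R2=0.0)


def gen_coculture_series(
    params: CRParams,
    state0: CRState | None = None,
    sample_days: Sequence[float] = (),
    noise: NoiseModel | None = None,
    solver: SolverConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Co-culture CFU trajectories of both ecotypes within one batch.

    Integrates a single batch (no dilution) sampled at ``sample_days``,
    converts biomass to CFU/mL via ``CFU_PER_BIOMASS``, and applies
    multiplicative lognormal noise.  Frame columns:
    time_days, species, cfu_per_ml, with species in
    {overproducer, auxotroph}.
    """
    noise = noise or NoiseModel()
    if state0 is None:
        state0 = DEFAULT_COCULTURE_STATE0
    days = np.asarray(sample_days, dtype=float)
    if days.size < 2 or np.any(np.diff(days) <= 0):
        raise ConfigError("sample_days must be increasing with >= 2 points")
    duration = float(days[-1])
    t_eval = days if days[0] == 0.0 else np.concatenate(([0.0], days))
    traj = integrate_batch(state0, params, duration, solver=solver, t_eval=t_eval)
    keep = np.isin(traj.times, days)
    rng = noise.rng(_STREAM_COCULTURE)
    rows = []
    for name, col in (("overproducer", traj.X1[keep]), ("auxotroph", traj.X2[keep])):
        cfu = col * CFU_PER_BIOMASS
        if noise.cfu_sigma_log > 0:
            cfu = cfu * np.exp(rng.normal(0.0, noise.cfu_sigma_log, size=cfu.shape))
        detect_limit = COUNTABLE_RANGE[0] * 1000.0 / _DEFAULT_PLATED_UL
        for t, v in zip(days, cfu):
            rows.append({"time_days": t, "species": name, "cfu_per_ml": v,
                         "below_detection": bool(v < detect_limit)})
    frame = pd.DataFrame(rows)
    meta = {
        "params": params.to_dict(),
        "state0": list(state0),
        "cfu_per_biomass": CFU_PER_BIOMASS,
        "cfu_sigma_log": noise.cfu_sigma_log,
        "seed": noise.seed,
    }
    return frame, meta


def coculture_qualitative_ok(frame: pd.DataFrame) -> bool:
    """Early overproducer dominance and delayed auxotroph recovery.

    True when the overproducer fraction exceeds 0.5 at day 1 and the
    auxotroph fraction at day 6 exceeds its fraction at day 1 (the regime
    the shipped default parameter set reproduces).
    """
    def frac_at(day):
        sub = frame[frame["time_days"] == day]
        aux = float(sub.loc[sub["species"] == "auxotroph", "cfu_per_ml"].sum())
        over = float(sub.loc[sub["species"] == "overproducer", "cfu_per_ml"].sum())
        if aux + over == 0:
            return np.nan
        return aux / (aux + over)

    f1, f6 = frac_at(1.0), frac_at(6.0)
    return bool(f1 < 0.5 and f6 > f1)


def _plate_counts(cfu: float, rng, sigma_log: float, plated_uL: float):
    """Simulate spot-plating: noisy CFU mapped onto the dilution ladder.

    Returns (count, dilution_factor, uncountable).  The reported count is the
    colony count at the lowest dilution bringing it into the countable range;
    below-range everywhere -> uncountable flag.
    """
    noisy = cfu * np.exp(rng.normal(0.0, sigma_log)) if sigma_log > 0 else cfu
    per_spot = noisy * plated_uL / 1000.0  # colonies on the undiluted spot
    lo, hi = COUNTABLE_RANGE
    for df in _DILUTION_LADDER:
        c = per_spot / df
        if c <= hi:
            if c < lo:
                return np.nan, 1.0, True
            return c, df, False
    return np.nan, 1.0, True  # above ladder range; practically unreachable


def gen_dilution_series(
    params: CRParams,
    state0: CRState,
    n_cycles: int,
    noise: NoiseModel | None = None,
    n_populations: int = 3,
    plated_volume_uL: float = _DEFAULT_PLATED_UL,
    solver: SolverConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Serial-dilution series: per-cycle observed frequencies plus count tables.

    Ground truth comes from :func:`feastfamine.model.iterate_map`; observed
    auxotroph frequencies are obtained by pushing noisy CFU draws through
    plate counting, so they inherit plating detection limits (uncountable
    flags) exactly as real spot plates would.

    Returns (freq_frame, count_table, metadata): freq_frame has columns
    cycle, population_id, aux_freq_true, aux_freq_observed; count_table is a
    metrics CountTable.
    """
    if n_cycles < 1:
        raise ConfigError(f"n_cycles must be >= 1, got {n_cycles}")
    noise = noise or NoiseModel()
    orbit = iterate_map(state0, params, n_cycles, solver=solver)
    rng = noise.rng(_STREAM_DILUTION)
    freq_rows, count_rows = [], []
    for k, (state, f_true) in enumerate(zip(orbit.states, orbit.aux_freq), start=1):
        day = k * params.dt_dilution
        for pop in range(1, n_populations + 1):
            obs_cfu = {}
            for eco, biomass in (("overproducer", state[0]), ("auxotroph", state[1])):
                cfu = biomass * CFU_PER_BIOMASS
                count, df, unc = _plate_counts(cfu, rng, noise.cfu_sigma_log, plated_volume_uL)
                count_rows.append({
                    "day": day, "population_id": pop, "ecotype": eco,
                    "dilution_factor": df, "count": count, "uncountable": unc,
                    "plated_volume_uL": plated_volume_uL,
                })
                obs_cfu[eco] = 0.0 if unc else count * df * 1000.0 / plated_volume_uL
            total = obs_cfu["auxotroph"] + obs_cfu["overproducer"]
            freq_rows.append({
                "cycle": k, "population_id": pop,
                "aux_freq_true": f_true,
                "aux_freq_observed": (obs_cfu["auxotroph"] / total) if total > 0 else np.nan,
            })
    meta = {
        "params": params.to_dict(),
        "state0": list(state0),
        "cfu_per_biomass": CFU_PER_BIOMASS,
        "cfu_sigma_log": noise.cfu_sigma_log,
        "countable_range": list(COUNTABLE_RANGE),
        "seed": noise.seed,
        "n_populations": n_populations,
    }
    return pd.DataFrame(freq_rows), pd.DataFrame(count_rows), meta


def recovery_theta() -> CRParams:
    """Ground-truth parameter set of the shipped calibration-recovery fixture.

    Constructed to be practically identifiable by the staged fitting
    procedure: the auxotroph does not compete for the primary resource
    (mu21 = 0, realising the second stage's assumption exactly), and the
    secondary-resource channel is gauge-fixed by treating the secretion rate
    p and the necromass fraction q as known constants (R2 is never observed
    directly, so its unit scale is otherwise a free gauge).
    """
    return CRParams(
        mu1=6.0, K1=0.8, mu21=0.0, K21=0.5, mu22=5.0, K22=0.3,
        Y1=1.0, Y21=0.7, Y22=1.0, p=0.0, q=0.6, d1=0.8, d2=0.5,
        D=0.1, S=10.0, dt_dilution=10.0,
    )


#: kinetic constants treated as known in the recovery fixture (gauge fix)
RECOVERY_FIXED = {"q": 0.6, "p": 0.0}

#: per-stage free parameters of the recovery fixture.  Y21 and K21 multiply
#: nothing when mu21 = 0 and are therefore structurally inert; mu21 itself is
#: freed in the global stage (competition introduced) and recovered at ~0.
RECOVERY_FREE = {
    "monoculture": ("mu1", "K1", "Y1", "d1"),
    "auxotroph": ("mu22", "K22", "Y22", "d2"),
    "global": ("mu1", "K1", "mu21", "mu22", "K22", "Y1", "Y22", "d1", "d2"),
    "dilution": ("mu1", "K1", "mu21", "mu22", "K22", "Y1", "Y22", "d1", "d2"),
}

#: dilution-experiment design of the recovery fixture: a monostable regime
#: (stable coexistence), so the frequency objective is smooth in parameters
RECOVERY_DILUTION_DT = 4.0

MONO_STATE0 = CRState(X1=0.05, X2=0.0, R1=10.0, R2=0.0)
CO_STATE0 = CRState(X1=0.05, X2=0.05, R1=10.0, R2=0.0)


def gen_recovery_dataset(noise: NoiseModel | None = None, n_cycles: int = 15) -> dict:
    """Synthetic observations of the recovery fixture for all four stages.

    Returns a dict with keys growth, coculture (observation frames in the
    calibration CSV schema), dilution (per-cycle frequency frame), plus the
    ground truth and the initial states used.
    """
    noise = noise or NoiseModel(od_sigma=0.0, cfu_sigma_log=0.0, seed=0)
    theta = recovery_theta()
    rng = noise.rng(3)  # dedicated stream

    def perturb(values):
        if noise.cfu_sigma_log > 0:
            return values * np.exp(rng.normal(0.0, noise.cfu_sigma_log, size=len(values)))
        return values

    times = np.round(np.arange(0.05, 3.01, 0.05), 3)
    traj = integrate_batch(MONO_STATE0, theta, 3.0,
                           t_eval=np.concatenate(([0.0], times)))
    keep = traj.times > 0
    growth = pd.DataFrame({
        "time_days": traj.times[keep],
        "species": "overproducer",
        "value": perturb(traj.X1[keep] * CFU_PER_BIOMASS),
        "value_type": "CFU_per_mL",
    })

    ct = np.round(np.arange(0.25, 10.01, 0.25), 3)
    traj2 = integrate_batch(CO_STATE0, theta, 10.0,
                            t_eval=np.concatenate(([0.0], ct)))
    keep2 = traj2.times > 0
    rows = []
    for species, col in (("overproducer", traj2.X1), ("auxotroph", traj2.X2)):
        vals = perturb(col[keep2] * CFU_PER_BIOMASS)
        rows += [{"time_days": t, "species": species, "value": v,
                  "value_type": "CFU_per_mL"}
                 for t, v in zip(traj2.times[keep2], vals)]
    coculture = pd.DataFrame(rows)

    theta_dil = theta.replace(dt_dilution=RECOVERY_DILUTION_DT)
    orbit = iterate_map(CO_STATE0, theta_dil, n_cycles)
    freq = orbit.aux_freq.copy()
    if noise.cfu_sigma_log > 0:
        # frequency noise from independent lognormal CFU draws per ecotype
        a = orbit.states[:, 1] * np.exp(rng.normal(0, noise.cfu_sigma_log, n_cycles))
        b = orbit.states[:, 0] * np.exp(rng.normal(0, noise.cfu_sigma_log, n_cycles))
        freq = a / (a + b)
    dilution = pd.DataFrame({"cycle": orbit.cycle_index, "aux_freq": freq})

    return {
        "theta": theta,
        "growth": growth,
        "coculture": coculture,
        "dilution": dilution,
        "mono_state0": MONO_STATE0,
        "co_state0": CO_STATE0,
        "dilution_dt": RECOVERY_DILUTION_DT,
        "seed": noise.seed,
    }


def write_artifact_csv(path, frame: pd.DataFrame, meta: dict) -> None:
    """Write a CSV with a YAML-front-matter-style header carrying metadata."""
    import yaml

    with open(path, "w") as fh:
        fh.write("# ---\n")
        for line in yaml.safe_dump(meta, sort_keys=True).splitlines():
            fh.write(f"# {line}\n")
        fh.write("# ---\n")
        frame.to_csv(fh, index=False)
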