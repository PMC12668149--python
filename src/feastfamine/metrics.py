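"""Empirical statistics for plate-count and growth-curve data.

Implements the field statistics used around serial-dilution co-culture
experiments: competitive selection rate, detection-limit imputation of
uncountable CFU spots, plate-count unit conversion, ecotype relative
frequencies, logistic growth-curve fitting, and per-interval growth rates.

Count tables are plain :class:`pandas.DataFrame` objects with the columns

``day, population_id, ecotype, dilution_factor, count, uncountable,
plated_volume_uL``

where ``ecotype`` is ``"auxotroph"`` or ``"overproducer"`` and
``uncountable`` is an explicit boolean flag (a spot below the detection
limit, not a true zero).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError, FitError, UnimputableError

__all__ = [
    "COUNT_TABLE_COLUMNS",
    "ECOTYPES",
    "GrowthFit",
    "validate_count_table",
    "selection_rate",
    "impute_zero_counts",
    "cfu_per_ml",
    "relative_frequencies",
    "fit_logistic_growth",
    "logistic_curve",
    "periodic_growth_rate",
]

COUNT_TABLE_COLUMNS = (
    "day", "population_id", "ecotype", "dilution_factor",
    "count", "uncountable", "plated_volume_uL",
)
ECOTYPES = ("auxotroph", "overproducer")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check CountTable invariants; returns the table unchanged."""
    missing = set(COUNT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"count table missing columns: {sorted(missing)}")
    bad_eco = set(table["ecotype"].unique()) - set(ECOTYPES)
    if bad_eco:
        raise DataError(f"unknown ecotypes: {sorted(bad_eco)}")
    if (table["dilution_factor"] < 1).any():
        raise DataError("dilution_factor must be >= 1")
    countable = table.loc[~table["uncountable"].astype(bool)]
    if not np.isfinite(countable["count"].to_numpy(dtype=float)).all():
        raise DataError("countable entries must have finite counts")
    keys = table[["day", "population_id", "ecotype", "dilution_factor"]]
    if keys.duplicated().any():
        raise DataError("(day, population, ecotype) keys must be unique per dilution")
    return table


def selection_rate(a_init: float, a_final: float, b_init: float, b_final: float,
                   days: float) -> float:
    """Competitive selection rate r (per day) of competitor A against B.

    r = [ln(a_final/a_init) - ln(b_final/b_init)] / days.  Counts must be
    positive (impute detection-limit zeros first); antisymmetric under
    swapping the competitors.
    """
    for name, v in (("a_init", a_init), ("a_final", a_final),
                    ("b_init", b_init), ("b_final", b_final)):
        if not v > 0:
            raise DataError(f"selection_rate requires positive counts; {name} = {v}")
    if not days > 0:
        raise DataError(f"days must be > 0, got {days}")
    return (math.log(a_final / a_init) - math.log(b_final / b_init)) / days


def impute_zero_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Replace uncountable spots by count 0.1 at the lowest countable parallel dilution.

    For each flagged (day, ecotype) the imputed entry gets count 0.1 at the
    minimum dilution factor over parallel populations (same day, same
    ecotype) that yielded a countable result.  Countable entries are returned
    untouched.  Raises :class:`UnimputableError` when no parallel countable
    result exists.
    """
    validate_count_table(table)
    out = table.copy()
    flagged = out["uncountable"].astype(bool)
    missing = []
    for idx in out.index[flagged]:
        day = out.at[idx, "day"]
        eco = out.at[idx, "ecotype"]
        parallel = out[
            (out["day"] == day)
            & (out["ecotype"] == eco)
            & (~out["uncountable"].astype(bool))
        ]
        if parallel.empty:
            missing.append((day, eco))
            continue
        out.at[idx, "count"] = 0.1
        out.at[idx, "dilution_factor"] = float(parallel["dilution_factor"].min())
        out.at[idx, "uncountable"] = False
    if missing:
        raise UnimputableError(
            f"no countable parallel population for {sorted(set(missing))}",
            missing=sorted(set(missing)),
        )
    return out


def cfu_per_ml(count: float, dilution_factor: float, plated_volume_uL: float) -> float:
    """Standard plate-count conversion: count · dilution · (1000 / plated µL)."""
    if not plated_volume_uL > 0:
        raise DataError(f"plated volume must be > 0, got {plated_volume_uL}")
    if not (count > 0 and dilution_factor > 0):
        raise DataError("count and dilution_factor must be positive")
    return count * dilution_factor * (1000.0 / plated_volume_uL)


def relative_frequencies(cfu_by_ecotype) -> dict:
    """Fractions of total CFU per ecotype; sums to 1.

    Accepts a mapping ecotype -> CFU/mL (or any labelled nonnegative values).
    """
    labels = list(cfu_by_ecotype)
    values = np.array([cfu_by_ecotype[k] for k in labels], dtype=float)
    if (values < 0).any():
        raise DataError("CFU values must be nonnegative")
    total = values.sum()
    if total <= 0:
        raise DataError("all-zero CFU input: no community to normalise")
    return dict(zip(labels, values / total))


@dataclasses.dataclass(frozen=True)
class GrowthFit:
    """Logistic growth-curve parameters: N(t) = K / (1 + ((K-N0)/N0) e^{-rt})."""

    K: float  #: carrying capacity (OD units)
    r: float  #: intrinsic rate (1/hr when times are hours)
    N0: float  #: initial size
    rss: float = 0.0  #: residual sum of squares of the fit

    def __post_init__(self):
        if not (self.K > 0 and self.r > 0 and self.N0 > 0):
            raise DataError(f"GrowthFit requires K, r, N0 > 0; got {self}")
        if self.N0 > self.K:
            raise DataError(f"GrowthFit requires N0 <= K; got N0={self.N0} > K={self.K}")


def logistic_curve(t, K: float, r: float, N0: float):
    """Logistic growth N(t) with carrying capacity K, rate r, inoculum N0."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


#: fitted r at/below this bound means no positive-growth solution exists
_R_FLOOR = 1e-6


def fit_logistic_growth(times: Sequence[float], od_values: Sequence[float]) -> GrowthFit:
    """Least-squares logistic fit to an optical-density growth curve.

    Initial guesses: K = max(od), N0 = first od, r from the log-linear slope
    of the early phase.  Raises :class:`FitError` on non-convergence or when
    the data admit no positive-growth solution (e.g. a decreasing series).
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(od_values, dtype=float)
    if t.size < 5:
        raise DataError(f"need >= 5 time points, got {t.size}")
    if (od <= 0).any():
        raise DataError("od_values must be positive")
    K0 = float(od.max())
    N00 = float(od[0])
    # early-phase log-linear slope over the first half-rise
    early = od <= N00 + 0.5 * (K0 - N00)
    r0 = 1.0
    if early.sum() >= 2 and np.ptp(t[early]) > 0:
        slope = np.polyfit(t[early], np.log(od[early]), 1)[0]
        if slope > 0:
            r0 = float(slope)
    x0 = (K0, r0, min(N00, 0.999 * K0))

    def resid(theta):
        K, r, N0 = theta
        return logistic_curve(t, K, r, N0) - od

    span = float(t[-1] - t[0]) if t[-1] > t[0] else 1.0
    sol = least_squares(
        resid, x0,
        bounds=([1e-12, _R_FLOOR, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"logistic fit did not converge: {sol.message}",
                       initial_guess=x0)
    K, r, N0 = sol.x
    if r <= _R_FLOOR * (1 + 1e-6) or r * span < 1e-3:
        raise FitError(
            "no positive-growth logistic solution (fitted rate at lower bound); "
            "is the series non-increasing?", initial_guess=x0,
        )
    return GrowthFit(K=float(K), r=float(r), N0=float(min(N0, K)),
                     rss=float(np.sum(sol.fun ** 2)))


def periodic_growth_rate(times: Sequence[float], values: Sequence[float]) -> np.ndarray:
    """Per-interval growth rate in percent change per day.

    For each consecutive pair: 100 · (N_{t2} - N_{t1}) / (N_{t1} · (t2 - t1)).
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(values, dtype=float)
    if t.size < 2:
        raise DataError("need at least 2 time points")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    if (n[:-1] <= 0).any():
        raise DataError("interval-start values must be positive")
    return 100.0 * np.diff(n) / (n[:-1] * np.diff(t))
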