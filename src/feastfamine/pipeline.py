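"""End-to-end desk-scale reproduction of the serial-dilution analysis.

``run_pipeline`` drives the whole study surface with one config:
a bifurcation scan of the calibrated map over the dilution interval, the
matching Lyapunov profile, and per-regime reports at the three reference
dilution intervals (exclusion, 3-period limit cycle, chaos).  All outputs
are deterministic CSV/JSON with the config hash and seed embedded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import chaos, model
from .errors import ConfigError

__all__ = ["RunConfig", "run_pipeline", "cr_frequency_map_factory"]

log = logging.getLogger("feastfamine.pipeline")

_ALLOWED_KEYS = {
    "model", "param_file", "dt_from", "dt_to", "dt_steps", "n_transient",
    "n_keep", "lyapunov_iter", "lyapunov_dts", "regime_dts", "seed",
    "with_figures", "log_level", "dry_run",
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full-analysis pipeline run.

    The dilution-interval grid defaults to 1–14 days, the plotted range of
    the study's bifurcation diagram; per-value Lyapunov exponents are
    computed on a coarser grid (they are ~10x the cost of the orbits).
    """

    model: str = "cr"
    param_file: Optional[str] = None  # None -> shipped default parameter set
    dt_from: float = 1.0
    dt_to: float = 14.0
    dt_steps: int = 27
    n_transient: int = 200
    n_keep: int = 100
    lyapunov_iter: int = 300
    lyapunov_dts: tuple = (2.0, 4.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0)
    regime_dts: tuple = (2.0, 9.0, 10.0)
    seed: int = 1
    with_figures: bool = False
    log_level: str = "INFO"
    dry_run: bool = False

    def __post_init__(self):
        if self.model not in ("cr", "glv"):
            raise ConfigError(f"model must be 'cr' or 'glv', got {self.model!r}")
        if not (self.dt_from > 0 and self.dt_to > self.dt_from):
            raise ConfigError("need 0 < dt_from < dt_to")
        if self.dt_steps < 1 or self.n_keep < 1 or self.n_transient < 0:
            raise ConfigError("dt_steps, n_keep must be >= 1; n_transient >= 0")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"bad log_level {self.log_level!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("lyapunov_dts", "regime_dts"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lyapunov_dts"] = list(self.lyapunov_dts)
        d["regime_dts"] = list(self.regime_dts)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def cr_frequency_map_factory(params: model.CRParams,
                             solver: model.SolverConfig | None = None):
    """Factory dt -> (4-vector post-transfer map), for bifurcation scans."""

    def factory(dt: float):
        return model.post_transfer_map(params.replace(dt_dilution=dt), solver=solver)

    return factory


def _aux_freq_observable(state) -> float:
    return model.aux_frequency(model.CRState.from_array(state))


def _header_lines(config: RunConfig) -> str:
    return (f"# config_hash: {config.config_hash}\n"
            f"# seed: {config.seed}\n")


def _write_csv(path: Path, frame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        frame.to_csv(fh, index=False, float_format="%.17g")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full desk-scale analysis bundle into ``outdir``.

    Writes params.json, diagram.csv, lyapunov.csv, regime_dt*.json and
    (optionally) figures; returns a manifest of artifact paths.  With
    ``config.dry_run`` the config is validated and the manifest returned
    without computing anything.
    """
    logging.basicConfig(level=config.log_level.upper())
    outdir = Path(outdir)
    manifest = {
        "params": outdir / "params.json",
        "diagram": outdir / "diagram.csv",
        "lyapunov": outdir / "lyapunov.csv",
        "regimes": {dt: outdir / f"regime_dt{dt:g}.json" for dt in config.regime_dts},
    }
    if config.dry_run:
        return manifest
    outdir.mkdir(parents=True, exist_ok=True)
    params = (model.load_params(config.param_file) if config.param_file
              else model.default_params())
    model.save_params(params, manifest["params"])
    x0 = model.STANDARD_STATE0.as_array()
    factory = cr_frequency_map_factory(params)

    t0 = time.time()
    grid = np.linspace(config.dt_from, config.dt_to, config.dt_steps)
    diagram = chaos.bifurcation_scan(
        factory, grid, n_transient=config.n_transient, n_keep=config.n_keep,
        x0=x0, observable=_aux_freq_observable,
    )
    _write_csv(manifest["diagram"], diagram.to_frame(), config)
    log.info("bifurcation scan: %d dt values in %.1fs", len(grid), time.time() - t0)

    t0 = time.time()
    lam_rows = []
    for dt in config.lyapunov_dts:
        res = chaos.largest_lyapunov(
            factory(dt), x0, n_transient=config.n_transient,
            n_iter=config.lyapunov_iter,
        )
        lam_rows.append({"scan_value": dt, "lambda_max": res.lambda_max,
                         "converged": res.converged})
    import pandas as pd

    _write_csv(manifest["lyapunov"], pd.DataFrame(lam_rows), config)
    log.info("lyapunov profile: %d dt values in %.1fs",
             len(config.lyapunov_dts), time.time() - t0)

    for dt in config.regime_dts:
        t0 = time.time()
        fn = factory(dt)
        orbit = model.iterate_map(model.STANDARD_STATE0,
                                  params.replace(dt_dilution=dt),
                                  config.n_transient + 3 * 32 + config.n_keep)
        tail = orbit.aux_freq[config.n_transient:]
        period = chaos.detect_period(tail, tol=1e-6, max_period=32)
        lam = chaos.largest_lyapunov(fn, x0, n_transient=config.n_transient,
                                     n_iter=max(config.lyapunov_iter, 300))
        report = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "dt": dt,
            "period": period,
            "aperiodic": period is None,
            "lambda_max": lam.lambda_max,
            "lyapunov_converged": lam.converged,
            "tail_min": float(tail.min()),
            "tail_max": float(tail.max()),
            "final_aux_freq": float(tail[-1]),
        }
        with open(manifest["regimes"][dt], "w") as fh:
            json.dump(report, fh, indent=1)
        log.info("regime report dt=%g in %.1fs: period=%s lambda=%.3f",
                 dt, time.time() - t0, period, lam.lambda_max)

    if config.with_figures:
        _plot_bundle(diagram, lam_rows, outdir)
        manifest["figure"] = outdir / "bifurcation.png"
    return manifest


def _plot_bundle(diagram, lam_rows, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 6),
                                   height_ratios=[2, 1])
    m, n_keep = diagram.kept_orbits.shape
    ax1.plot(np.repeat(diagram.scan_values, n_keep),
             diagram.kept_orbits.ravel(), ",k", alpha=0.5)
    ax1.set_ylabel("auxotroph relative frequency")
    dts = [r["scan_value"] for r in lam_rows]
    lams = [r["lambda_max"] for r in lam_rows]
    ax2.axhline(0.0, color="grey", lw=0.8)
    ax2.plot(dts, lams, "o-")
    ax2.set_xlabel("dilution interval Δt (days)")
    ax2.set_ylabel("λ_max (nats/iter)")
    fig.tight_layout()
    fig.savefig(outdir / "bifurcation.png", dpi=150)
    plt.close(fig)
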