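"""Nested calibration: objectives, stage contracts, parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from feastfamine.calibration import (
    FitConfig,
    FitResult,
    ObservationMapping,
    PENALTY_LOSS,
    abundance_sse,
    calibrate_dilution,
    fit_auxotroph,
    fit_global,
    fit_monoculture,
    loss_log_sse,
)
from feastfamine.errors import ConfigError, DataError
from feastfamine.model import CRState, integrate_batch, iterate_map
from feastfamine.synth import (
    CFU_PER_BIOMASS,
    NoiseModel,
    RECOVERY_FIXED,
    RECOVERY_FREE,
    gen_recovery_dataset,
    recovery_theta,
)

NOISELESS = NoiseModel(od_sigma=0.0, cfu_sigma_log=0.0, seed=0)


@pytest.fixture(scope="module")
def dataset():
    return gen_recovery_dataset(NOISELESS)


@pytest.fixture(scope="module")
def mono_mapping(dataset):
    return ObservationMapping(state0=dataset["mono_state0"],
                              cfu_per_biomass=CFU_PER_BIOMASS)


@pytest.fixture(scope="module")
def co_mapping(dataset):
    return ObservationMapping(state0=dataset["co_state0"],
                              cfu_per_biomass=CFU_PER_BIOMASS)


def stage_config(stage, **kw):
    kw.setdefault("seed", 1)
    kw.setdefault("free_params", RECOVERY_FREE[stage])
    kw.setdefault("fixed_values", RECOVERY_FIXED)
    return FitConfig(stage=stage, **kw)


@pytest.fixture(scope="module")
def stage1(dataset, mono_mapping):
    return fit_monoculture(dataset["growth"],
                           stage_config("monoculture", max_evals=2000),
                           mono_mapping)


@pytest.fixture(scope="module")
def stage2(dataset, stage1, co_mapping):
    return fit_auxotroph(dataset["coculture"], stage1,
                         stage_config("auxotroph", max_evals=2500), co_mapping)


@pytest.fixture(scope="module")
def stage3(dataset, stage2, co_mapping):
    return fit_global(dataset["coculture"], stage2,
                      stage_config("global", max_evals=4000), co_mapping)


class TestLossLogSse:
    def test_self_consistency_is_zero(self, dataset, co_mapping):
        loss = loss_log_sse(dataset["coculture"], dataset["theta"], co_mapping)
        assert loss < 1e-10

    def test_doubling_observations_adds_n_ln2_squared(self, dataset, co_mapping):
        obs = dataset["coculture"]
        doubled = obs.assign(value=2.0 * obs["value"])
        base = loss_log_sse(obs, dataset["theta"], co_mapping)
        shifted = loss_log_sse(doubled, dataset["theta"], co_mapping)
        assert shifted - base == pytest.approx(len(obs) * math.log(2.0) ** 2, rel=1e-4)

    def test_perturbed_params_always_lose_to_truth(self, dataset, co_mapping):
        theta = dataset["theta"]
        base = loss_log_sse(dataset["coculture"], theta, co_mapping)
        rng = np.random.default_rng(1)
        for _ in range(50):
            factors = rng.uniform(0.7, 1.3, size=4)
            pert = theta.replace(mu1=theta.mu1 * factors[0],
                                 mu22=theta.mu22 * factors[1],
                                 d1=theta.d1 * factors[2],
                                 Y22=theta.Y22 * factors[3])
            if pert == theta:
                continue
            assert loss_log_sse(dataset["coculture"], pert, co_mapping) > base

    def test_simulation_failure_returns_penalty_not_exception(self, dataset, co_mapping):
        # astronomically stiff parameters blow the integrator budget or
        # produce nonpositive simulated biomass at observed times
        bad = dataset["theta"].replace(d2=5e8, mu22=0.0)
        loss = loss_log_sse(dataset["coculture"], bad, co_mapping)
        assert math.isfinite(loss)

    def test_nonpositive_observations_rejected(self, dataset, co_mapping):
        obs = dataset["coculture"].copy()
        obs.loc[obs.index[0], "value"] = 0.0
        with pytest.raises(DataError):
            loss_log_sse(obs, dataset["theta"], co_mapping)


class TestFitMonoculture:
    def test_recovers_growth_and_yield_parameters(self, dataset, stage1):
        theta = dataset["theta"]
        assert stage1.params.mu1 == pytest.approx(theta.mu1, rel=0.05)
        assert stage1.params.Y1 == pytest.approx(theta.Y1, rel=0.05)
        assert stage1.params.d1 == pytest.approx(theta.d1, rel=0.05)

    def test_trace_best_so_far_non_increasing(self, stage1):
        losses = [v for _, v in stage1.trace]
        assert all(b <= a for a, b in zip(losses, losses[1:]))

    def test_flat_series_flagged_non_identifiable(self, mono_mapping):
        flat = pd.DataFrame({
            "time_days": np.linspace(0.5, 3.0, 10),
            "species": "overproducer",
            "value": 5e8,
            "value_type": "CFU_per_mL",
        })
        res = fit_monoculture(flat, stage_config("monoculture", max_evals=300),
                              mono_mapping)
        assert res.diagnostics.get("non_identifiable") is True

    def test_wrong_species_rejected(self, dataset, mono_mapping):
        with pytest.raises(DataError):
            fit_monoculture(dataset["coculture"],
                            stage_config("monoculture", max_evals=300),
                            mono_mapping)

    def test_noisy_replicates_recover_mu1(self, mono_mapping):
        noisy = gen_recovery_dataset(NoiseModel(cfu_sigma_log=0.05, seed=1))
        res = fit_monoculture(noisy["growth"],
                              stage_config("monoculture", max_evals=2000),
                              mono_mapping)
        assert res.params.mu1 == pytest.approx(recovery_theta().mu1, rel=0.15)


class TestFitAuxotroph:
    def test_overproducer_parameters_bit_identical(self, stage1, stage2):
        for name in ("mu1", "K1", "Y1", "d1"):
            assert getattr(stage2.params, name) == getattr(stage1.params, name)

    def test_no_competition_enforced(self, stage2):
        assert stage2.params.mu21 == 0.0

    def test_recovers_auxotroph_channel(self, dataset, stage2):
        theta = dataset["theta"]
        assert stage2.params.mu22 == pytest.approx(theta.mu22, rel=0.05)
        assert stage2.params.d2 == pytest.approx(theta.d2, rel=0.05)

    def test_mutated_prior_rejected(self, dataset, stage1, co_mapping):
        bad_prior = FitResult(params=stage1.params, loss_value=stage1.loss_value,
                              stage="global", fixed_from_prior=(), trace=[])
        with pytest.raises(ConfigError):
            fit_auxotroph(dataset["coculture"], bad_prior,
                          stage_config("auxotroph", max_evals=300), co_mapping)


class TestFitGlobal:
    def test_loss_not_worse_than_prior(self, dataset, stage2, stage3, co_mapping):
        prior_loss = loss_log_sse(dataset["coculture"], stage2.params, co_mapping)
        assert stage3.loss_value <= prior_loss + 1e-12

    def test_all_free_kinetics_recovered_within_ten_percent(self, dataset, stage3):
        theta = dataset["theta"]
        for name in RECOVERY_FREE["global"]:
            got = getattr(stage3.params, name)
            want = getattr(theta, name)
            if want == 0.0:
                assert abs(got) < 0.05, name
            else:
                assert got == pytest.approx(want, rel=0.10), name

    def test_same_seed_reproduces_result(self, dataset, stage2, co_mapping):
        cfg = stage_config("global", max_evals=400)
        a = fit_global(dataset["coculture"], stage2, cfg, co_mapping)
        b = fit_global(dataset["coculture"], stage2, cfg, co_mapping)
        assert a.params == b.params
        assert a.loss_value == b.loss_value


class TestCalibrateDilution:
    def test_data_from_prior_params_keeps_prior(self, dataset, co_mapping):
        theta = dataset["theta"].replace(dt_dilution=dataset["dilution_dt"])
        prior = FitResult(params=theta, loss_value=0.0, stage="global",
                          fixed_from_prior=(), trace=[])
        res = calibrate_dilution(dataset["dilution"], prior,
                                 stage_config("dilution", max_evals=300,
                                              n_samples=20),
                                 dataset["co_state0"],
                                 dt_dilution=dataset["dilution_dt"])
        assert res.loss_value < 1e-10

    def test_degenerate_box_returns_prior(self, dataset):
        theta = dataset["theta"].replace(dt_dilution=dataset["dilution_dt"])
        prior = FitResult(params=theta, loss_value=0.0, stage="global",
                          fixed_from_prior=(), trace=[])
        res = calibrate_dilution(dataset["dilution"], prior,
                                 stage_config("dilution", max_evals=1,
                                              n_samples=1, box_width=0.0),
                                 dataset["co_state0"],
                                 dt_dilution=dataset["dilution_dt"])
        for name in RECOVERY_FREE["dilution"]:
            assert getattr(res.params, name) == pytest.approx(
                getattr(theta, name), rel=1e-12)

    def test_improves_on_shifted_prior_inside_box(self, dataset, stage3):
        res = calibrate_dilution(dataset["dilution"], stage3,
                                 stage_config("dilution", max_evals=600,
                                              n_samples=40),
                                 dataset["co_state0"],
                                 dt_dilution=dataset["dilution_dt"])
        prior_sse = abundance_sse(
            dataset["dilution"],
            stage3.params.replace(dt_dilution=dataset["dilution_dt"]),
            dataset["co_state0"])
        assert res.loss_value <= prior_sse + 1e-12


class TestFitConfigValidation:
    def test_unknown_stage_rejected(self):
        with pytest.raises(ConfigError):
            FitConfig(stage="extra")

    def test_non_kinetic_free_params_rejected(self):
        with pytest.raises(ConfigError):
            FitConfig(stage="global", free_params=("S",))

    def test_overlapping_free_and_fixed_rejected(self):
        with pytest.raises(ConfigError):
            FitConfig(stage="global", free_params=("mu1",),
                      fixed_values={"mu1": 2.0})
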