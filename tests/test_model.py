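"""Consumer-resource batch dynamics, transfer rule, and serial-dilution map."""

import numpy as np
import pytest

from feastfamine.errors import ConfigError, InvalidStateError
from feastfamine.model import (
    CRParams,
    CRState,
    STANDARD_STATE0,
    apply_transfer,
    aux_frequency,
    cr_rhs,
    integrate_batch,
    iterate_map,
    post_transfer_map,
)
from conftest import random_valid_params


def reference_rhs(state, p):
    """Independent transcription of the model equations (oracle)."""
    X1, X2, R1, R2 = state
    monod1 = p.mu1 * R1 / (p.K1 + R1)
    monod21 = p.mu21 * R1 / (p.K21 + R1)
    monod22 = p.mu22 * R2 / (p.K22 + R2)
    return (
        (monod1 - p.d1) * X1,
        (monod21 + monod22 - p.d2) * X2,
        -monod1 * X1 / p.Y1 - monod21 * X2 / p.Y21,
        p.p * X1 + p.q * p.d1 * X1 - monod22 * X2 / p.Y22,
    )


class TestCrRhs:
    def test_zero_resources_leave_only_death_and_sources(self, simple_params):
        d = cr_rhs(CRState(1.0, 1.0, 0.0, 0.0), simple_params)
        p = simple_params
        assert d[0] == pytest.approx(-p.d1)
        assert d[1] == pytest.approx(-p.d2)
        assert d[2] == 0.0
        assert d[3] == pytest.approx(p.p + p.q * p.d1)

    def test_saturated_growth_limit(self, simple_params):
        p = simple_params
        d = cr_rhs(CRState(1.0, 0.0, 1e12, 0.0), p)
        assert d[0] == pytest.approx(p.mu1 - p.d1, rel=1e-10)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = random_valid_params(rng)
            s = CRState(*rng.uniform(0.01, 5.0, size=4))
            got = cr_rhs(s, p)
            want = reference_rhs(s, p)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_r1_never_produced(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_valid_params(rng)
            s = CRState(*rng.uniform(0.0, 10.0, size=4))
            assert cr_rhs(s, p)[2] <= 0.0

    def test_nonfinite_state_rejected(self, simple_params):
        with pytest.raises(InvalidStateError):
            cr_rhs(CRState(np.nan, 1.0, 1.0, 1.0), simple_params)
        with pytest.raises(InvalidStateError):
            cr_rhs(CRState(1.0, np.inf, 1.0, 1.0), simple_params)


class TestIntegrateBatch:
    def test_empty_culture_is_constant(self, simple_params):
        traj = integrate_batch(CRState(0.0, 0.0, 5.0, 2.0), simple_params, 3.0)
        np.testing.assert_allclose(traj.states[-1], [0.0, 0.0, 5.0, 2.0], atol=1e-9)

    def test_monoculture_yield_conservation(self, simple_params):
        p = simple_params.replace(d1=0.0, p=0.0, q=0.0)
        s0 = CRState(0.05, 0.0, 10.0, 0.0)
        traj = integrate_batch(s0, p, 2.0)
        # X1 + Y1*R1 conserved when death/secretion are off
        invariant = traj.X1 + p.Y1 * traj.R1
        np.testing.assert_allclose(invariant, invariant[0], rtol=1e-6)
        gain = traj.X1[-1] - s0.X1
        spent = p.Y1 * (s0.R1 - traj.R1[-1])
        assert gain == pytest.approx(spent, rel=1e-6)

    def test_terminal_state_matches_fixed_step_rk4(self, simple_params):
        s0 = CRState(0.05, 0.05, 10.0, 0.0)
        duration = 2.0
        traj = integrate_batch(s0, simple_params, duration)

        # independent fixed-step RK4 integrator as oracle
        def rhs(y):
            return np.array(reference_rhs(y, simple_params))

        n_steps = 20000
        h = duration / n_steps
        y = s0.as_array()
        for _ in range(n_steps):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.testing.assert_allclose(traj.states[-1], y, rtol=1e-5, atol=1e-8)

    def test_r1_monotone_nonincreasing_within_batch(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_valid_params(rng)
            traj = integrate_batch(STANDARD_STATE0, p, p.dt_dilution, n_points=301)
            assert np.all(np.diff(traj.R1) <= 1e-9 * max(1.0, traj.R1[0]))

    def test_duration_must_be_positive(self, simple_params, state0):
        with pytest.raises(ConfigError):
            integrate_batch(state0, simple_params, 0.0)


class TestApplyTransfer:
    def test_stated_arithmetic(self, simple_params):
        s = apply_transfer(CRState(10.0, 20.0, 5.0, 4.0), simple_params)
        assert s == pytest.approx((1.0, 2.0, 9.5, 0.4))

    def test_supply_concentration_is_fixed_point(self, simple_params):
        s = apply_transfer(CRState(1.0, 1.0, simple_params.S, 0.0), simple_params)
        assert s.R1 == pytest.approx(simple_params.S)

    def test_extinction_absorbing(self, simple_params):
        s = apply_transfer(CRState(0.0, 0.0, 0.0, 0.0), simple_params)
        assert s == pytest.approx((0.0, 0.0, 0.9 * simple_params.S, 0.0))


class TestIterateMap:
    def test_single_cycle_is_composition(self, simple_params, state0):
        orbit = iterate_map(state0, simple_params, 1)
        end = integrate_batch(state0, simple_params,
                              simple_params.dt_dilution,
                              t_eval=[0.0, simple_params.dt_dilution]).final_state
        manual = apply_transfer(end, simple_params)
        np.testing.assert_allclose(orbit.states[0], manual, rtol=1e-10, atol=1e-12)

    def test_orbit_matches_manual_composition(self, simple_params, state0):
        n = 5
        orbit = iterate_map(state0, simple_params, n)
        s = state0
        for k in range(n):
            end = integrate_batch(s, simple_params, simple_params.dt_dilution,
                                  t_eval=[0.0, simple_params.dt_dilution]).final_state
            s = apply_transfer(end, simple_params)
            np.testing.assert_allclose(orbit.states[k], s, rtol=1e-12, atol=1e-14)

    def test_absent_auxotroph_stays_absent(self, simple_params):
        orbit = iterate_map(CRState(0.05, 0.0, 10.0, 0.0), simple_params, 8)
        assert np.all(orbit.aux_freq == 0.0)
        assert np.all(orbit.states[:, 1] == 0.0)

    def test_deterministic_bit_identical(self, simple_params, state0):
        a = iterate_map(state0, simple_params, 10)
        b = iterate_map(state0, simple_params, 10)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.aux_freq, b.aux_freq)

    def test_aux_freq_recomputable(self, simple_params, state0):
        orbit = iterate_map(state0, simple_params, 6)
        recomputed = orbit.states[:, 1] / (orbit.states[:, 0] + orbit.states[:, 1])
        np.testing.assert_allclose(orbit.aux_freq, recomputed, atol=1e-12)

    def test_orbit_nonnegative_on_random_params(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            p = random_valid_params(rng)
            orbit = iterate_map(STANDARD_STATE0, p, 12)
            assert np.all(orbit.states >= 0.0)

    def test_post_transfer_map_consistency(self, simple_params, state0):
        fn = post_transfer_map(simple_params)
        orbit = iterate_map(state0, simple_params, 3)
        y = fn(fn(fn(state0.as_array())))
        np.testing.assert_allclose(y, orbit.states[-1], rtol=1e-9, atol=1e-12)


class TestParamsIO:
    def test_round_trip(self, tmp_path, simple_params):
        from feastfamine.model import load_params, save_params

        path = tmp_path / "p.json"
        save_params(simple_params, path)
        assert load_params(path) == simple_params

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            CRParams.from_dict({**CRParams(
                mu1=1, K1=1, mu21=0, K21=1, mu22=1, K22=1,
                Y1=1, Y21=1, Y22=1, p=0, q=0, d1=0, d2=0).to_dict(),
                "extra_rate": 3.0})

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            CRParams(mu1=-1, K1=1, mu21=0, K21=1, mu22=1, K22=1,
                     Y1=1, Y21=1, Y22=1, p=0, q=0, d1=0, d2=0)
        with pytest.raises(ConfigError):
            CRParams(mu1=1, K1=1, mu21=0, K21=1, mu22=1, K22=1,
                     Y1=1, Y21=1, Y22=1, p=0, q=1.5, d1=0, d2=0)
        with pytest.raises(ConfigError):
            CRParams(mu1=1, K1=1, mu21=0, K21=1, mu22=1, K22=1,
                     Y1=1, Y21=1, Y22=1, p=0, q=0, d1=0, d2=0, D=1.0)


def test_aux_frequency_empty_community_is_zero():
    assert aux_frequency(CRState(0.0, 0.0, 1.0, 0.0)) == 0.0
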