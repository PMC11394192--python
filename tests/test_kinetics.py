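"""Degradation-rate fitting, Arrhenius scaling, shelf life and effective temperature."""

import math

import numpy as np
import pytest

from osmofreeze import (
    ArrheniusModel,
    IsothermalSeries,
    RateEstimate,
    effective_temperature,
    fit_arrhenius,
    fit_rate,
    make_cycle_profile,
    predict_nonisothermal,
    presets,
    rate_at,
    relative_error,
    shelf_life,
)


def _series(times, values, T=-18.0, name="q"):
    return IsothermalSeries(name, T, tuple(times), tuple(values))


class TestRateFitting:
    def test_exact_first_order(self):
        t = np.arange(0.0, 105.0, 15.0)
        est = fit_rate(_series(t, 100 * np.exp(-0.02 * t)), "first")
        assert est.k == pytest.approx(0.02, rel=1e-12)
        assert est.intercept == pytest.approx(100.0, rel=1e-10)
        assert est.r2 == pytest.approx(1.0)

    def test_exact_zero_order(self):
        t = np.arange(0.0, 60.0, 10.0)
        est = fit_rate(_series(t, 9 - 0.05 * t), "zero")
        assert est.k == pytest.approx(0.05, rel=1e-12)
        assert est.intercept == pytest.approx(9.0)

    def test_nls_option_matches_loglinear_on_clean_data(self):
        t = np.arange(0.0, 105.0, 15.0)
        s = _series(t, 50 * np.exp(-0.01 * t))
        assert fit_rate(s, "first", method="nls").k == pytest.approx(
            fit_rate(s, "first").k, rel=1e-6
        )

    def test_replicated_noisy_recovery(self):
        # 7 timepoints x 3 replicates, 5% multiplicative noise: the median
        # estimate over many simulated studies should land within 10% of truth
        k_true, t_grid = 0.01, np.repeat(np.linspace(0, 120, 7), 3)
        ks = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            v = 100 * np.exp(-k_true * t_grid) * rng.lognormal(0.0, 0.05, t_grid.size)
            ks.append(fit_rate(_series(t_grid, v), "first").k)
        assert np.median(ks) == pytest.approx(k_true, rel=0.10)

    def test_no_degradation_warns_and_flags(self):
        t = np.arange(0.0, 50.0, 10.0)
        with pytest.warns(UserWarning, match="no degradation"):
            est = fit_rate(_series(t, 5 + 0.01 * t), "zero")
        assert not est.degradation_detected
        assert est.k <= 0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            fit_rate(_series([0, 1, 2], [1.0, 0.0, -1.0]), "first")
        with pytest.raises(ValueError, match="distinct"):
            fit_rate(_series([0, 0, 1], [3, 3, 2]), "zero")
        with pytest.raises(ValueError):
            IsothermalSeries("q", -5, (3.0, 1.0, 2.0), (1.0, 2.0, 3.0))


class TestArrhenius:
    def test_two_point_closed_form(self):
        rates = [
            RateEstimate(0.002, "first", -23.0, 100.0, 1.0, 0.0),
            RateEstimate(0.02, "first", -5.0, 100.0, 1.0, 0.0),
        ]
        model = fit_arrhenius(rates)
        assert model.E_a / 1000 == pytest.approx(71.34, abs=0.01)
        assert model.k_ref == pytest.approx(0.00392, abs=0.00001)

    def test_equal_rates_give_zero_activation_energy(self):
        rates = [
            RateEstimate(0.01, "first", T, 1.0, 1.0, 0.0) for T in (-5.0, -14.0, -23.0)
        ]
        model = fit_arrhenius(rates)
        assert model.E_a == pytest.approx(0.0, abs=1e-9)
        assert model.k_ref == pytest.approx(0.01, rel=1e-10)

    @pytest.mark.parametrize("key", sorted(presets.KINETIC_PRESETS))
    def test_noiseless_round_trip_recovers_presets(self, key):
        truth = presets.KINETIC_PRESETS[key]
        rates = [
            RateEstimate(rate_at(truth, T), truth.order, T, 1.0, 1.0, 0.0)
            for T in presets.STORAGE_TEMPERATURES_C
        ]
        model = fit_arrhenius(rates)
        assert model.E_a == pytest.approx(truth.E_a, rel=1e-3)
        assert model.k_ref == pytest.approx(truth.k_ref, rel=1e-3)

    def test_error_conditions(self):
        one = [RateEstimate(0.01, "first", -5.0, 1.0, 1.0, 0.0)]
        with pytest.raises(ValueError, match="2 distinct"):
            fit_arrhenius(one)
        mixed = one + [RateEstimate(0.002, "zero", -23.0, 1.0, 1.0, 0.0)]
        with pytest.raises(ValueError, match="[Mm]ixed"):
            fit_arrhenius(mixed)


class TestRateAndShelfLife:
    def test_rate_at_reference_is_exact(self):
        m = ArrheniusModel(k_ref=0.0033, E_a=88.8e3)
        assert rate_at(m, -18.0) == pytest.approx(0.0033, rel=1e-14)

    @pytest.mark.parametrize(
        "T, expected", [(-5.0, 0.0251), (-23.0, 0.00143)]
    )
    def test_rate_at_direct_values(self, T, expected):
        m = ArrheniusModel(k_ref=0.0033, E_a=88.8e3)
        assert rate_at(m, T) == pytest.approx(expected, abs=0.0002)

    def test_rate_strictly_increasing_in_temperature(self):
        m = ArrheniusModel(k_ref=0.0025, E_a=115.6e3)
        Ts = np.linspace(-40, 0, 81)
        ks = rate_at(m, Ts)
        assert np.all(np.diff(ks) > 0)

    def test_first_order_shelf_life_half_loss(self):
        m = ArrheniusModel(
            k_ref=0.0033, E_a=88.8e3, order="first", initial_value=100, limit_value=50
        )
        assert shelf_life(m, -18.0) == pytest.approx(math.log(2) / 0.0033, rel=1e-12)
        assert shelf_life(m, -18.0) == pytest.approx(210.0, abs=0.1)

    def test_zero_order_shelf_life(self):
        m = ArrheniusModel(
            k_ref=0.009, E_a=57.1e3, order="zero", initial_value=9, limit_value=4
        )
        assert shelf_life(m, -18.0) == pytest.approx(5 / 0.009, rel=1e-12)

    def test_shelf_life_strictly_decreasing_in_temperature(self):
        for key in (("vitamin_c", "od"), ("sensory", "untreated")):
            m = presets.KINETIC_PRESETS[key]
            sls = [shelf_life(m, T) for T in np.linspace(-30, -2, 29)]
            assert all(a > b for a, b in zip(sls, sls[1:]))

    def test_limit_above_initial_rejected(self):
        m = ArrheniusModel(k_ref=0.01, E_a=8e4, order="first",
                           initial_value=10, limit_value=10)
        with pytest.raises(ValueError):
            shelf_life(m, -18.0)


class TestEffectiveTemperature:
    CYCLE = [(-12.0, 24.0), (-5.0, 24.0), (-8.0, 24.0)]

    def test_constant_profile_is_identity(self):
        prof = make_cycle_profile([(-8.0, 24.0)], 1)
        m = ArrheniusModel(k_ref=0.0033, E_a=88.8e3)
        assert effective_temperature(prof, m) == pytest.approx(-8.0, abs=1e-10)

    def test_reference_cycle_value(self):
        prof = make_cycle_profile(self.CYCLE, 1)
        m = ArrheniusModel(k_ref=0.0033, E_a=88.8e3)
        assert effective_temperature(prof, m) == pytest.approx(-7.8, abs=0.05)

    def test_bracketing_and_jensen_bound(self):
        # the repeated temperature-abuse cycle: T_eff lies inside the
        # temperature range and above the arithmetic time-weighted mean
        prof = make_cycle_profile(self.CYCLE, 3)
        for ea in (30e3, 88.8e3, 200e3):
            m = ArrheniusModel(k_ref=0.0033, E_a=ea)
            teff = effective_temperature(prof, m)
            assert -12.0 < teff < -5.0
            assert teff > prof.time_weighted_mean_c() == pytest.approx(-25 / 3)

    def test_repeat_invariance(self):
        m = ArrheniusModel(k_ref=0.0033, E_a=88.8e3)
        one = effective_temperature(make_cycle_profile(self.CYCLE, 1), m)
        three = effective_temperature(make_cycle_profile(self.CYCLE, 3), m)
        assert one == pytest.approx(three, abs=1e-12)

    def test_monotone_in_activation_energy(self):
        prof = make_cycle_profile(self.CYCLE, 1)
        eas = np.linspace(10e3, 300e3, 30)
        teffs = [
            effective_temperature(prof, ArrheniusModel(k_ref=0.01, E_a=ea))
            for ea in eas
        ]
        assert all(a < b for a, b in zip(teffs, teffs[1:]))

    def test_zero_activation_energy_harmonic_mean(self):
        prof = make_cycle_profile(self.CYCLE, 1)
        m = ArrheniusModel(k_ref=0.01, E_a=0.0)
        with pytest.warns(UserWarning, match="harmonic"):
            teff = effective_temperature(prof, m)
        inv = np.mean([1 / (273.15 + T) for T, _ in self.CYCLE])
        assert teff == pytest.approx(1 / inv - 273.15, abs=1e-9)


class TestNonIsothermalPrediction:
    def test_constant_profile_matches_isothermal_closed_form(self):
        m = ArrheniusModel(k_ref=0.0033, E_a=88.8e3, order="first", initial_value=100)
        prof = make_cycle_profile([(-10.0, 48.0)], 1)
        traj = predict_nonisothermal(m, prof)
        expected = 100 * math.exp(-rate_at(m, -10.0) * 2.0)
        assert traj["value"].iloc[-1] == pytest.approx(expected, rel=1e-14)

    def test_two_segment_first_order_arithmetic(self):
        # one day at each of two temperatures where k = 0.01 and 0.03 per day
        from scipy.optimize import brentq

        m = ArrheniusModel(k_ref=0.01, E_a=88.8e3, order="first", initial_value=1.0)

        T_high = brentq(lambda T: rate_at(m, T) - 0.03, -18.0, 30.0)
        prof = make_cycle_profile([(-18.0, 24.0), (T_high, 24.0)], 1)
        traj = predict_nonisothermal(m, prof)
        assert traj["value"].iloc[-1] == pytest.approx(math.exp(-0.04), rel=1e-9)

    @pytest.mark.parametrize("key", [("vitamin_c", "od"), ("sensory", "od")])
    def test_profile_equals_constant_teff_run(self, key):
        m = presets.KINETIC_PRESETS[key]
        prof = make_cycle_profile([(-12.0, 24.0), (-5.0, 24.0), (-8.0, 24.0)], 3)
        traj = predict_nonisothermal(m, prof)
        teff = effective_temperature(prof, m)
        k = rate_at(m, teff)
        if m.order == "first":
            expected = m.initial_value * math.exp(-k * prof.total_days)
        else:
            expected = m.initial_value - k * prof.total_days
        assert traj["value"].iloc[-1] == pytest.approx(expected, rel=1e-10)

    def test_zero_order_flags_below_limit_without_flooring(self):
        m = ArrheniusModel(k_ref=0.5, E_a=57.1e3, order="zero",
                           initial_value=5.0, limit_value=4.0)
        prof = make_cycle_profile([(-5.0, 24.0 * 30)], 1)
        traj = predict_nonisothermal(m, prof)
        assert traj["value"].iloc[-1] < 4.0
        assert bool(traj["below_limit"].iloc[-1])


class TestRelativeError:
    @pytest.mark.parametrize(
        "k_exp, k_fit, expected",
        [(0.01, 0.01, 0.0), (0.010, 0.012, -20.0), (0.010, 0.015, -50.0)],
    )
    def test_values(self, k_exp, k_fit, expected):
        assert relative_error(k_exp, k_fit) == pytest.approx(expected)

    def test_acceptance_threshold_semantics(self):
        assert abs(relative_error(0.010, 0.012)) <= 20.0  # boundary accepted
        assert abs(relative_error(0.010, 0.015)) > 20.0

    def test_zero_experimental_rejected(self):
        with pytest.raises(ValueError):
            relative_error(0.0, 0.01)
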