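"""Virtual-patient model: fluxes, kinetics, conservation and integration."""

import math

import numpy as np
import pytest

from aiis import BolusInsulinModel, ChallengeEvent, PatientParams, PatientState
from aiis.params import ConfigError
from aiis.patient import (IntegrationError, InvalidEventError, VirtualPatient,
                          gastric_emptied_mass, gastric_emptying_flux,
                          glucose_balance, gut_absorption, insulin_kinetics,
                          iv_insulin_bolus, net_hepatic_glucose_balance,
                          peripheral_utilization, renal_excretion)


# ---------------------------------------------------------------- gastric

class TestGastricEmptying:
    def test_no_pending_meal_gives_zero_flux(self, patient):
        ev = ChallengeEvent("meal_complex_CHO", t_start=100.0, amount=50.0)
        assert gastric_emptying_flux(PatientState(t=50.0), ev, patient) == 0.0

    @pytest.mark.parametrize("kind", ["meal_complex_CHO", "oral_glucose"])
    @pytest.mark.parametrize("grams", [5.0, 50.0])
    def test_total_emptied_mass_equals_meal(self, patient, kind, grams):
        ev = ChallengeEvent(kind, t_start=0.0, amount=grams)
        # numeric integration oracle of the profile
        t = np.arange(0.0, 600.0, 0.02)
        flux = np.array([gastric_emptying_flux(PatientState(t=ti), ev, patient)
                         for ti in t])
        total = np.trapezoid(flux, t)
        assert total == pytest.approx(grams * 1000.0, rel=1e-4)
        assert gastric_emptied_mass(ev, patient, 2000.0) == pytest.approx(
            grams * 1000.0, rel=1e-9)

    def test_half_mass_at_profile_midpoint(self, patient):
        """The trapezoid is symmetric, so its midpoint splits the mass in half."""
        ev = ChallengeEvent("oral_glucose", t_start=0.0, amount=50.0)
        vmax = patient.gastric_vmax
        duration = 50_000.0 / vmax + patient.gastric_ramp
        half = gastric_emptied_mass(ev, patient, duration / 2.0)
        assert half == pytest.approx(25_000.0, rel=1e-9)

    def test_negative_amount_rejected(self):
        with pytest.raises(InvalidEventError):
            ChallengeEvent("oral_glucose", t_start=0.0, amount=-1.0)

    def test_complex_cho_slower_than_oral_glucose(self, patient):
        meal = ChallengeEvent("meal_complex_CHO", 0.0, 50.0)
        sugar = ChallengeEvent("oral_glucose", 0.0, 50.0)
        s = PatientState(t=patient.gastric_ramp + 10.0)
        assert (gastric_emptying_flux(s, meal, patient)
                < gastric_emptying_flux(s, sugar, patient))


# ------------------------------------------------------------- absorption

class TestGutAbsorption:
    def test_empty_gut_absorbs_nothing(self, patient):
        assert gut_absorption(PatientState(Ggut=0.0), patient) == 0.0

    def test_saturates_at_configured_maximum(self, patient):
        g_in = gut_absorption(PatientState(Ggut=1e12), patient)
        expected = 60.0 * patient.gut_absorption_vmax / patient.glucose_volume_dl
        assert g_in == pytest.approx(expected, rel=1e-3)

    def test_meal_mass_is_conserved_through_the_gut(self, patient):
        """Everything emptied into the gut eventually appears systemically."""
        model = VirtualPatient(
            patient, events=[ChallengeEvent("oral_glucose", 10.0, 50.0)])
        dt, t, ggut, absorbed = 0.05, 0.0, 0.0, 0.0
        while t < 1440.0:
            f_in = model.meal_emptying(t)
            f_out = (patient.gut_absorption_vmax * ggut
                     / (patient.gut_absorption_half + ggut))
            ggut += dt * (f_in - f_out)
            absorbed += dt * f_out
            t += dt
        assert absorbed + ggut == pytest.approx(50_000.0, rel=1e-3)
        assert absorbed == pytest.approx(50_000.0, rel=1e-3)


# ------------------------------------------------------------ utilization

class TestPeripheralUtilization:
    def test_zero_insulin_leaves_insulin_independent_uptake(self, patient):
        assert peripheral_utilization(100.0, 0.0, patient) == pytest.approx(
            patient.insulin_independent_util)

    def test_slope_in_insulin_is_c_at_reference(self, patient):
        """At the reference glycemia the insulin slope equals 60*c (per hour)."""
        g = patient.glucose_ref
        slope = (peripheral_utilization(g, 21.0, patient)
                 - peripheral_utilization(g, 20.0, patient))
        assert slope == pytest.approx(60.0 * patient.c, rel=1e-9)

    def test_doubling_sp_doubles_insulin_dependent_component(self, patient):
        from dataclasses import replace
        p2 = replace(patient, Sp=min(1.0, 2.0 * patient.Sp))
        base = patient.insulin_independent_util
        dep1 = peripheral_utilization(140.0, 30.0, patient) - base
        dep2 = peripheral_utilization(140.0, 30.0, p2) - base
        assert dep2 == pytest.approx(2.0 * dep1, rel=1e-9)

    @pytest.mark.parametrize("g_pair", [(80.0, 120.0), (120.0, 200.0)])
    def test_monotone_in_glucose_and_insulin(self, patient, g_pair):
        lo, hi = g_pair
        assert (peripheral_utilization(hi, 20.0, patient)
                >= peripheral_utilization(lo, 20.0, patient))
        assert (peripheral_utilization(lo, 25.0, patient)
                >= peripheral_utilization(lo, 20.0, patient))


# ------------------------------------------------------------------ NHGB

class TestNHGB:
    def test_high_insulin_means_net_hepatic_uptake(self, patient):
        assert net_hepatic_glucose_balance(100.0, 2000.0, patient) < 0.0

    def test_zero_insulin_means_maximal_production(self, patient):
        top = max(v for _, v in patient.nhgb_table)
        assert net_hepatic_glucose_balance(100.0, 0.0, patient) == pytest.approx(top)

    def test_monotone_in_hepatic_sensitivity(self, patient):
        from dataclasses import replace
        lo = replace(patient, Sh=0.3)
        hi = replace(patient, Sh=0.7)
        for i in (10.0, 30.0, 80.0, 200.0):
            assert (net_hepatic_glucose_balance(100.0, i, lo)
                    >= net_hepatic_glucose_balance(100.0, i, hi))

    def test_monotone_non_increasing_in_glucose(self, patient):
        for g1, g2 in [(60.0, 80.0), (80.0, 100.0), (100.0, 140.0), (140.0, 200.0)]:
            assert (net_hepatic_glucose_balance(g1, 20.0, patient)
                    >= net_hepatic_glucose_balance(g2, 20.0, patient))

    def test_bounded_by_table_endpoints(self, patient):
        scale = patient.body_weight / patient.nhgb_weight_ref
        values = [v for _, v in patient.nhgb_table]
        for g in (10.0, 100.0, 400.0):
            for i in (0.0, 50.0, 5000.0):
                v = net_hepatic_glucose_balance(g, i, patient)
                assert min(values) * scale <= v <= max(values) * scale


# ----------------------------------------------------------------- renal

class TestRenalExcretion:
    def test_below_threshold_no_excretion(self, patient):
        assert renal_excretion(100.0, patient) == 0.0
        assert renal_excretion(patient.renal_threshold, patient) == 0.0

    def test_linear_above_threshold(self, patient):
        thr = patient.renal_threshold
        one = renal_excretion(thr + 10.0, patient)
        two = renal_excretion(thr + 20.0, patient)
        assert two == pytest.approx(2.0 * one, rel=1e-12)


# --------------------------------------------------------------- insulin

class TestInsulinKinetics:
    def test_zero_infusion_zero_state_stays_zero(self, patient):
        dI, dIa = insulin_kinetics(0.0, 0.0, 0.0, patient)
        assert dI == 0.0 and dIa == 0.0

    def test_steady_state_matches_closed_form(self, patient):
        """Constant infusion R converges to I = R/(k_el*V_I) within 1%."""
        model = VirtualPatient(patient)
        for rate in (16.667, 50.0, 120.0):
            state = PatientState(G=100.0, I=0.0)
            for _ in range(12_000):   # 1000 min at dt = 1/12
                state = model.step(state, rate, 0.0, 1.0 / 12.0)
            expected = rate / (patient.insulin_elim_rate
                               * patient.insulin_dist_volume)
            assert state.I == pytest.approx(expected, rel=1e-2)
            assert state.Ia == pytest.approx(
                expected * patient.active_insulin_rates[0]
                / patient.active_insulin_rates[1], rel=1e-2)

    def test_zero_input_decay_matches_exponential(self, patient):
        model = VirtualPatient(patient)
        state = PatientState(G=0.0, I=100.0, Ia=0.0)
        dt, n = 0.1, 300
        for _ in range(n):
            state = model.step(state, 0.0, 0.0, dt)
        assert state.I == pytest.approx(
            100.0 * math.exp(-patient.insulin_elim_rate * n * dt), abs=1e-6)

    def test_negative_infusion_rejected(self, patient):
        with pytest.raises(ValueError):
            insulin_kinetics(10.0, 10.0, -1.0, patient)


class TestIvInsulinBolus:
    def test_initial_concentration_is_dose_over_v1(self):
        m = BolusInsulinModel()
        assert iv_insulin_bolus(10.0, 0.0, m) == pytest.approx(
            10_000.0 / m.V1, rel=1e-12)

    def test_decays_to_zero(self):
        m = BolusInsulinModel()
        assert iv_insulin_bolus(10.0, 5000.0, m) == pytest.approx(0.0, abs=1e-9)

    def test_auc_matches_closed_form(self):
        """Numerically integrated exposure equals dose/(k_el*V1)."""
        m = BolusInsulinModel()
        t = np.linspace(0.0, 600.0, 600_001)
        c = np.array([iv_insulin_bolus(10.0, ti, m) for ti in t[::50]])
        auc = np.trapezoid(c, t[::50])
        assert auc == pytest.approx(10_000.0 / (m.k_el * m.V1), rel=1e-3)


# ------------------------------------------------------------ dG/dt & step

class TestGlucoseBalance:
    def test_all_zero_fluxes_give_zero(self, patient):
        assert glucose_balance(0.0, 0.0, 0.0, 0.0, 0.0, patient) == 0.0

    def test_balanced_fluxes_give_zero(self, patient):
        w, v = patient.body_weight, patient.glucose_volume_dl
        g_out = 100.0
        nhgb = g_out * w            # mg/h production balancing utilization
        assert glucose_balance(0.0, nhgb, g_out, 0.0, 0.0, patient) == (
            pytest.approx(0.0, abs=1e-9))

    def test_uncompensated_iv_bolus_raises_g_by_dose_over_volume(self, patient):
        """10 g into V_g with all fluxes frozen at zero: dG integrates to 10,000/V_g."""
        rate = 10_000.0 / 0.5       # mg/min over 30 s
        dgdt_h = glucose_balance(0.0, 0.0, 0.0, 0.0, rate, patient)
        delta = dgdt_h / 60.0 * 0.5
        assert delta == pytest.approx(10_000.0 / patient.glucose_volume_dl,
                                      rel=1e-12)


class TestStep:
    def test_dt_must_be_positive(self, patient):
        with pytest.raises(ValueError):
            VirtualPatient(patient).step(PatientState(), 0.0, 0.0, 0.0)

    def test_nan_state_raises_named_integration_error(self, patient):
        model = VirtualPatient(patient)
        with pytest.raises(IntegrationError, match="G"):
            model.step(PatientState(G=float("nan")), 0.0, 0.0, 0.1)

    def test_halving_dt_barely_changes_trajectory(self, patient):
        """Fixed-step RK4 is converged: dt -> dt/2 moves G by < 0.5 mg/dL."""
        model = VirtualPatient(
            patient, events=[ChallengeEvent("oral_glucose", 30.0, 50.0)])

        def simulate(dt, horizon=360.0):
            state = PatientState(G=100.0, I=18.6, Ia=18.6)
            out = []
            while state.t < horizon - 1e-9:
                state = model.step(state, 16.667, 0.0, dt)
                out.append(state.G)
            return np.array(out)

        coarse = simulate(1.0 / 12.0)
        fine = simulate(1.0 / 24.0)
        assert np.max(np.abs(coarse - fine[1::2])) < 0.5

    def test_production_matches_tiny_step_euler_oracle(self, patient):
        """RK4 at dt=1/12 min tracks an explicit-Euler reference at dt=0.001."""
        events = [ChallengeEvent("meal_complex_CHO", 60.0, 50.0)]
        model = VirtualPatient(patient, events=events)
        horizon = 360.0

        # production integrator
        state = PatientState(G=100.0, I=18.6, Ia=18.6)
        rk4 = {}
        while state.t < horizon - 1e-9:
            state = model.step(state, 16.667, 0.0, 1.0 / 12.0)
            rk4[round(state.t * 12)] = state.G

        # independent explicit-Euler oracle
        y = [100.0, 18.6, 18.6, 0.0]
        t, dt = 0.0, 0.001
        checkpoints = {}
        n = int(round(horizon / dt))
        for i in range(n):
            d = model.derivatives(t, tuple(y), 16.667, 0.0)
            y = [max(a + dt * b, 0.0) for a, b in zip(y, d)]
            t = (i + 1) * dt
            if i % 5000 == 4999:   # every 5 minutes
                checkpoints[round(t * 12)] = y[0]

        diffs = [abs(rk4[k] - g) for k, g in checkpoints.items() if k in rk4]
        assert diffs and max(diffs) < 0.1

    def test_validation_rejects_out_of_range_sensitivities(self):
        with pytest.raises(ConfigError):
            PatientParams(Sh=1.5).validate()
        with pytest.raises(ConfigError):
            PatientParams(Sp=-0.1).validate()
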