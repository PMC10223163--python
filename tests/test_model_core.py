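"""Structural-model tests: disposition constants, the two simulation routes,
their closed-form limits, mass balance and steady state."""
import numpy as np
import pytest

import rivddi as rd
from rivddi.model import simulate_analytic, simulate_ode, steady_state_profile

from conftest import random_valid_params


def rel_dev(a: np.ndarray, b: np.ndarray) -> float:
    """Maximum deviation relative to the peak concentration."""
    scale = max(np.max(np.abs(a)), np.max(np.abs(b)))
    return float(np.max(np.abs(a - b)) / scale) if scale > 0 else 0.0


class TestMacroConstants:
    def test_human_control_values(self, human_control):
        mc = rd.macro_constants(human_control)
        # direct arithmetic from the extrapolated human parameters
        assert mc.k10 == pytest.approx(human_control.cl_f / 42.06, rel=1e-12)
        assert mc.k10 == pytest.approx(0.2147, rel=1e-3)
        assert mc.k12 == pytest.approx(0.2344, rel=1e-3)
        assert mc.k21 == pytest.approx(0.02935, rel=1e-3)

    def test_vieta_identities_random_params(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            mc = rd.macro_constants(p)
            s = mc.k10 + mc.k12 + mc.k21
            assert mc.alpha + mc.beta == pytest.approx(s, rel=1e-10)
            assert mc.alpha * mc.beta == pytest.approx(mc.k10 * mc.k21, rel=1e-10)
            assert mc.alpha > mc.beta > 0

    def test_symmetric_case(self):
        p = rd.ModelParameters(cl_f=5.0, vc_f=10.0, q_f=5.0, vp_f=10.0,
                               ka=1.0, d2=2.0, f1=0.5, alag2=0.0)
        mc = rd.macro_constants(p)
        assert mc.k12 == pytest.approx(mc.k10)
        assert mc.k10 == pytest.approx(mc.k21 * (p.vp_f / p.vc_f))

    def test_invalid_parameters_raise(self):
        with pytest.raises(rd.InvalidParameterError):
            rd.ModelParameters(cl_f=-1.0, vc_f=42.0, q_f=9.9, vp_f=336.0,
                               ka=0.97, d2=6.6, f1=0.26, alag2=0.5)
        with pytest.raises(rd.InvalidParameterError):
            rd.ModelParameters(cl_f=9.0, vc_f=42.0, q_f=9.9, vp_f=336.0,
                               ka=0.97, d2=6.6, f1=1.3, alag2=0.5)


class TestSimulation:
    def test_zero_dose_gives_zero(self, human_control):
        reg = rd.DoseRegimen(dose=0.0, tau=24.0, n_doses=3)
        t = np.linspace(0, 72, 100)
        assert np.all(simulate_analytic(human_control, reg, t).conc == 0.0)
        assert np.all(simulate_ode(human_control, reg, t).conc == 0.0)

    def test_auc_inf_equals_dose_over_clearance(self, human_control):
        # AUC to 2000 h (~ 40 terminal half-lives) must match 1000 * D / CL
        reg = rd.DoseRegimen(dose=20.0)
        t = np.concatenate([np.arange(0, 48, 0.05), np.arange(48, 2000, 0.5)])
        prof = simulate_analytic(human_control, reg, t)
        auc = np.trapezoid(prof.conc, prof.times)
        assert auc == pytest.approx(1000.0 * 20.0 / human_control.cl_f, rel=5e-3)
        assert 1000.0 * 20.0 / human_control.cl_f == pytest.approx(2214.8, rel=1e-3)

    def test_bateman_limit(self):
        # f1 = 1 and vanishing inter-compartmental exchange reduce the model
        # to the one-compartment first-order-absorption (Bateman) equation
        p = rd.ModelParameters(cl_f=9.03, vc_f=42.06, q_f=1e-7, vp_f=336.0,
                               ka=0.97, d2=6.62, f1=1.0, alag2=0.501)
        t = np.arange(0.0, 48.0, 0.1)
        prof = simulate_analytic(p, rd.DoseRegimen(dose=20.0), t)
        k = p.cl_f / p.vc_f
        bateman = (1000.0 * 20.0 * p.ka) / (p.vc_f * (p.ka - k)) * (
            np.exp(-k * t) - np.exp(-p.ka * t))
        assert rel_dev(prof.conc, bateman) < 1e-3

    def test_no_input_before_lag(self, human_control):
        p = human_control.replace(f1=0.0)
        t = np.linspace(0.0, p.alag2 * 0.99, 25)
        prof = simulate_analytic(p, rd.DoseRegimen(dose=20.0), t)
        assert np.all(prof.conc == 0.0)

    def test_ode_matches_analytic_multidose(self, human_control):
        reg = rd.DoseRegimen(dose=20.0, tau=24.0, n_doses=7)
        t = np.arange(0.0, 7 * 24.0, 0.1)
        pa = simulate_analytic(human_control, reg, t)
        po = simulate_ode(human_control, reg, t)
        assert rel_dev(pa.conc, po.conc) < 1e-3

    def test_ode_matches_analytic_random_params(self, rng):
        reg = rd.DoseRegimen(dose=10.0, tau=24.0, n_doses=2)
        t = np.arange(0.0, 48.0, 0.25)
        for _ in range(20):
            p = random_valid_params(rng)
            pa = simulate_analytic(p, reg, t)
            po = simulate_ode(p, reg, t)
            assert rel_dev(pa.conc, po.conc) < 1e-3

    def test_linearity_in_dose(self, human_control, rng):
        t = np.arange(0.0, 48.0, 0.2)
        for _ in range(3):
            p = random_valid_params(rng)
            c1 = simulate_analytic(p, rd.DoseRegimen(dose=5.0), t).conc
            c2 = simulate_analytic(p, rd.DoseRegimen(dose=10.0), t).conc
            np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-12, atol=1e-12)

    def test_mass_balance(self, human_control):
        reg = rd.DoseRegimen(dose=20.0, tau=24.0, n_doses=3)
        t = np.arange(0.0, 72.0, 0.25)
        _, states = simulate_ode(human_control, reg, t, return_states=True)
        total_in_system = states.sum(axis=0)  # depot + central + peripheral + eliminated
        p = human_control
        r0 = (1.0 - p.f1) * reg.dose / p.d2
        cum_input = np.zeros_like(t)
        for td in reg.dose_times:
            cum_input += p.f1 * reg.dose * (t >= td)
            cum_input += r0 * np.clip(t - td - p.alag2, 0.0, p.d2)
        # amounts jump at dose instants; check balance strictly between them
        between = ~np.isin(t, reg.dose_times)
        assert np.max(np.abs(total_in_system - cum_input)[between]) < 1e-3 * reg.dose

    def test_terminal_slope_approaches_beta(self, human_control):
        mc = rd.macro_constants(human_control)
        t = np.arange(400.0, 500.0, 1.0)
        prof = simulate_analytic(human_control, rd.DoseRegimen(dose=20.0), t)
        slope = np.polyfit(t, np.log(prof.conc), 1)[0]
        assert -slope == pytest.approx(mc.beta, rel=1e-3)


class TestSteadyState:
    def test_interval_auc_is_dose_over_clearance(self, human_control):
        ss = steady_state_profile(human_control, 20.0, 24.0)
        auc = np.trapezoid(ss.conc, ss.times)
        assert auc == pytest.approx(1000.0 * 20.0 / human_control.cl_f, rel=5e-3)
        assert ss.meta["method"] == "superposition"

    def test_accumulation_dominates_first_dose(self, human_control):
        t = np.arange(0.0, 24.01, 0.05)
        first = simulate_analytic(human_control, rd.DoseRegimen(dose=20.0), t)
        ss = steady_state_profile(human_control, 20.0, 24.0, times=t)
        assert np.all(ss.conc >= first.conc - 1e-9)

    def test_dose_proportionality(self, human_control):
        ss1 = steady_state_profile(human_control, 10.0, 24.0)
        ss2 = steady_state_profile(human_control, 20.0, 24.0)
        np.testing.assert_allclose(ss2.conc, 2.0 * ss1.conc, rtol=1e-10)

    def test_superposition_agrees_with_repeat_dosing(self, human_test):
        t = np.arange(0.0, 24.01, 0.1)
        exact = steady_state_profile(human_test, 20.0, 24.0, times=t)
        iterated = steady_state_profile(human_test, 20.0, 24.0, times=t,
                                        method="repeat", auc_rtol=1e-5)
        assert iterated.meta["method"] == "repeat"
        assert np.max(np.abs(exact.conc - iterated.conc)) / np.max(exact.conc) < 5e-3

    def test_non_convergence_raises(self, human_control):
        with pytest.raises(rd.ConvergenceError):
            steady_state_profile(human_control, 20.0, 24.0, method="repeat",
                                 max_doses=3, auc_rtol=1e-9)
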