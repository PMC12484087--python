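"""Circuit ODE right-hand side, integrators, and analytic limiting cases."""

import numpy as np
import pytest

from photodipole.membrane_model import (
    CircuitCoefficients,
    MembraneParams,
    Trace,
    eq1_rhs,
    instantaneous_cap_step,
    integrate,
    integrate_euler_oracle,
    integrate_rk4,
    relaxation_closed_form,
)
from photodipole.photokinetics import LightProtocol, PhotoswitchParams, build_coefficients


def const_coeffs(cm=25.0, vs=0.0, dcm=0.0, dvs=0.0):
    return CircuitCoefficients(
        cm_of_t=lambda t: cm + 0.0 * np.asarray(t),
        dcm_dt=lambda t: dcm + 0.0 * np.asarray(t),
        vs_of_t=lambda t: vs + 0.0 * np.asarray(t),
        dvs_dt=lambda t: dvs + 0.0 * np.asarray(t),
    )


class TestRHS:
    def test_rest_is_stationary(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        assert eq1_rhs(-60.0, 0.0, const_coeffs(cm=25.0), params) == pytest.approx(0.0)

    def test_capacitive_term_hand_evaluation(self):
        # dVm/dt = -dCm/dt * (Vm - Vs)/Cm with vm at rest and vs = 0
        params = MembraneParams(cm0=26.7, rm=1e9, vr=-60.0)  # leak negligible
        rhs = eq1_rhs(-60.0, 0.0, const_coeffs(cm=26.7, dcm=-1.0), params)
        assert rhs == pytest.approx(-(-1.0) * (-60.0) / 26.7, rel=1e-12)
        assert rhs == pytest.approx(-2.2472, abs=1e-4)

    def test_leak_term_hand_evaluation(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        assert eq1_rhs(-70.0, 0.0, const_coeffs(cm=25.0), params) == pytest.approx(0.4)

    @pytest.mark.parametrize("bad_vm", [float("nan"), float("inf")])
    def test_nonfinite_vm_rejected(self, bad_vm):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        with pytest.raises(ValueError):
            eq1_rhs(bad_vm, 0.0, const_coeffs(), params)

    def test_nonpositive_capacitance_rejected(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        with pytest.raises(ValueError):
            eq1_rhs(-60.0, 0.0, const_coeffs(cm=-1.0), params)


class TestIntegrate:
    def test_constant_coefficients_flat_at_rest(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        tr = integrate(const_coeffs(), params, (0.0, 100.0), 20.0)
        assert np.max(np.abs(tr.v - (-60.0))) < 1e-9

    def test_matches_rc_relaxation_closed_form(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)  # tau = 25 ms
        tr = integrate(const_coeffs(), params, (0.0, 200.0), 20.0, vm0=-70.0)
        expected = relaxation_closed_form(-70.0, params, tr.t)
        assert np.max(np.abs(tr.v - expected)) <= 1e-6

    def test_rk4_matches_adaptive_on_protocol(self, cfg):
        coeffs = build_coefficients(cfg.membrane, cfg.photoswitch, cfg.protocol)
        ad = integrate(coeffs, cfg.membrane, cfg.simulation.window, cfg.simulation.rate)
        rk = integrate_rk4(coeffs, cfg.membrane, cfg.simulation.window, cfg.simulation.rate)
        assert np.max(np.abs(ad.v - rk.v)) < 1e-4

    def test_empty_span_rejected(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        with pytest.raises(ValueError):
            integrate(const_coeffs(), params, (10.0, 10.0), 20.0)


class TestEulerOracle:
    def test_flat_trace_constant_coefficients(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        tr = integrate_euler_oracle(const_coeffs(), params, (0.0, 10.0), dt=0.001)
        assert np.max(np.abs(tr.v - (-60.0))) < 1e-12

    def test_large_step_rejected(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        with pytest.raises(ValueError):
            integrate_euler_oracle(const_coeffs(), params, (0.0, 10.0), dt=0.5)


class TestAnalyticLimits:
    def test_cap_step_conserves_charge(self):
        # -15 % capacitance drop on a -60 mV membrane with zero surface potential
        assert instantaneous_cap_step(-60.0, 0.0, 26.7, 22.7) == pytest.approx(-70.57, abs=0.01)

    def test_cap_step_no_stored_charge(self):
        assert instantaneous_cap_step(-12.5, -12.5, 30.0, 10.0) == pytest.approx(-12.5)

    def test_cap_step_identity(self):
        assert instantaneous_cap_step(-60.0, 5.0, 25.0, 25.0) == pytest.approx(-60.0)

    def test_cap_step_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            instantaneous_cap_step(-60.0, 0.0, -1.0, 22.7)

    def test_relaxation_endpoints(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0)
        assert relaxation_closed_form(-70.0, params, 0.0) == pytest.approx(-70.0)
        assert relaxation_closed_form(-70.0, params, 25.0) == pytest.approx(-63.679, abs=1e-3)
        assert relaxation_closed_form(-70.0, params, 1e5) == pytest.approx(-60.0)


def fast_step_params(**kw):
    base = dict(dcm_rel=0.0, dvs=0.0, tau_on_c=0.01, tau_off_c=50.0,
                tau_on_s=0.01, tau_off_s=50.0)
    base.update(kw)
    return PhotoswitchParams(**base)


class TestFastStepLimits:
    """tau -> 0 limits of the two light-driven terms."""

    protocol = LightProtocol(t_on=50.0, duration=2.0)

    def test_fast_vs_step_shifts_vm_by_amplitude(self):
        params = MembraneParams(cm0=25.0, rm=1.0, vr=-60.0, vs0=0.0)
        ps = fast_step_params(dvs=5.0)
        coeffs = build_coefficients(params, ps, self.protocol)
        tr = integrate(coeffs, params, (0.0, 50.3), 100.0)
        before = tr.v[tr.t <= 50.0][-1]
        after = tr.v[np.searchsorted(tr.t, 50.2)]
        assert after - before == pytest.approx(5.0, rel=0.01)

    def test_fast_cm_step_matches_charge_conservation(self):
        params = MembraneParams(cm0=26.67, rm=1.0, vr=-60.0, vs0=0.0)
        ps = fast_step_params(dcm_rel=-0.15)
        coeffs = build_coefficients(params, ps, self.protocol)
        tr = integrate(coeffs, params, (0.0, 50.3), 100.0)
        after = tr.v[np.searchsorted(tr.t, 50.2)]
        expected = instantaneous_cap_step(-60.0, 0.0, 26.67, 26.67 * 0.85)
        assert after == pytest.approx(expected, rel=0.01)


class TestTrace:
    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            Trace(t=np.array([0.0, 0.05, 0.2]), v=np.zeros(3), rate=20.0)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            Trace(t=np.array([0.0, 0.1, 0.05]), v=np.zeros(3), rate=20.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Trace(t=np.arange(4) / 20.0, v=np.zeros(3), rate=20.0)

    def test_membrane_invariants(self):
        with pytest.raises(ValueError):
            MembraneParams(cm0=-5.0, rm=1.0, vr=-60.0)
        with pytest.raises(ValueError):
            MembraneParams(cm0=25.0, rm=0.0, vr=-60.0)
        assert MembraneParams(cm0=25.0, rm=1.0, vr=-60.0).tau == pytest.approx(25.0)
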