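"""Minimum-jerk ramps, tracking metrics, and the admittance environment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from twinplat.errors import (
    DivergenceError,
    InvalidParameterError,
    MetricUndefinedError,
)
from twinplat.platform_model import (
    AdmittanceSpec,
    PerturbationSpec,
    estimate_simulated_stiffness,
    minimum_jerk_ramp,
    minimum_jerk_velocity,
    ramp_tracking_metrics,
    simulate_admittance,
    sinusoid_command,
    sinusoid_pair,
)
from twinplat.signals import TimeSeries

FS = 2000.0


class TestMinimumJerkRamp:
    def test_protocol_ramp_peaks_at_45_deg_per_s(self):
        spec = PerturbationSpec(amplitude_deg=3.0, duration_s=0.125)
        assert spec.peak_velocity_deg_s == pytest.approx(45.0, abs=1e-12)
        # dense numerical maximization of the analytic velocity
        t = np.linspace(0, spec.duration_s, 200001)
        assert minimum_jerk_velocity(spec, t).max() == pytest.approx(45.0, abs=1e-6)

    def test_boundary_conditions(self):
        spec = PerturbationSpec(amplitude_deg=2.0, duration_s=0.2)
        ramp = minimum_jerk_ramp(spec, FS)
        i_end = int(round(spec.duration_s * FS))
        assert ramp.values[0] == 0.0
        assert ramp.values[i_end] == pytest.approx(2.0, abs=1e-12)
        assert ramp.values[-1] == pytest.approx(2.0, abs=1e-12)  # holds at A
        v = minimum_jerk_velocity(spec, np.array([0.0, spec.duration_s]))
        np.testing.assert_allclose(v, 0.0, atol=1e-12)

    @given(
        amplitude=st.floats(0.5, 6.0),
        duration=st.floats(0.1, 1.0),
    )
    def test_peak_velocity_closed_form_matches_grid_search(self, amplitude, duration):
        if 1.875 * amplitude / duration > 100.0:
            return  # outside the perturbation speed envelope
        spec = PerturbationSpec(amplitude_deg=amplitude, duration_s=duration)
        t = np.linspace(0, duration, 20001)
        peak = minimum_jerk_velocity(spec, t).max()
        assert peak == pytest.approx(1.875 * amplitude / duration, rel=1e-6)

    def test_rom_limit_enforced(self):
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(amplitude_deg=16.0, duration_s=1.0, direction="DP")
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(amplitude_deg=11.0, duration_s=1.0, direction="IE")

    def test_speed_cap_enforced(self):
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(amplitude_deg=10.0, duration_s=0.125)  # 150 deg/s

    def test_underresolved_ramp_rejected(self):
        spec = PerturbationSpec(amplitude_deg=3.0, duration_s=0.125)
        with pytest.raises(InvalidParameterError):
            minimum_jerk_ramp(spec, fs=50.0)


class TestRampTrackingMetrics:
    @pytest.fixture
    def ideal(self):
        return minimum_jerk_ramp(PerturbationSpec(hold_s=0.2), FS)

    def test_identity_gives_zero_metrics(self, ideal):
        phase, sse = ramp_tracking_metrics(ideal, ideal)
        assert phase == pytest.approx(0.0, abs=1e-12)
        assert sse == pytest.approx(0.0, abs=1e-12)

    def test_pure_delay_appears_in_phase_not_sse(self, ideal):
        delay = 10  # samples = 5 ms
        vals = np.concatenate([np.zeros(delay), ideal.values])[: len(ideal)]
        measured = TimeSeries(vals, fs=FS)
        phase, sse = ramp_tracking_metrics(measured, ideal)
        assert phase == pytest.approx(delay / FS, rel=1e-6)
        assert sse == pytest.approx(0.0, abs=1e-9)

    def test_constant_hold_offset_appears_in_sse(self, ideal):
        i_end = int(round(0.125 * FS))
        vals = ideal.values.copy()
        vals[i_end:] += 0.05
        phase, sse = ramp_tracking_metrics(TimeSeries(vals, fs=FS), ideal)
        assert sse == pytest.approx(0.05, rel=1e-6)

    def test_invariant_to_common_delay(self, ideal):
        delay = 40
        def delayed(ts):
            v = np.concatenate([np.zeros(delay), ts.values])[: len(ts)]
            return TimeSeries(v, fs=FS)
        lag = 6
        meas = np.concatenate([np.zeros(lag), ideal.values])[: len(ideal)]
        measured = TimeSeries(meas, fs=FS)
        p0, s0 = ramp_tracking_metrics(measured, ideal)
        p1, s1 = ramp_tracking_metrics(delayed(measured), delayed(ideal))
        assert p1 == pytest.approx(p0, abs=1e-9)
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_unreached_threshold_is_an_error(self, ideal):
        measured = TimeSeries(ideal.values * 0.5, fs=FS)  # tops out at 1.5 deg
        with pytest.raises(MetricUndefinedError):
            ramp_tracking_metrics(measured, ideal)


class TestAdmittanceSimulation:
    def test_zero_torque_stays_at_rest(self):
        spec = AdmittanceSpec(k_sim=500.0)
        tau = TimeSeries(np.zeros(1000), fs=FS)
        np.testing.assert_allclose(simulate_admittance(spec, tau).values, 0.0)

    def test_constant_torque_settles_at_tau_over_k(self):
        spec = AdmittanceSpec(k_sim=500.0)
        tau = TimeSeries(np.full(int(2 * FS), 50.0), fs=FS)
        theta = simulate_admittance(spec, tau)
        assert theta.values[-1] == pytest.approx(0.1, rel=1e-9)

    def test_matches_adaptive_integrator_oracle(self):
        spec = AdmittanceSpec(k_sim=2000.0)
        duration = 1.0
        tau0 = 100.0
        tau = TimeSeries(np.full(int(duration * FS) + 1, tau0), fs=FS)
        theta = simulate_admittance(spec, tau)

        def rhs(t, y):
            return [y[1], (tau0 - spec.b_sim * y[1] - spec.k_sim * y[0]) / spec.i_sim]

        sol = solve_ivp(rhs, (0, duration), [0.0, 0.0], rtol=1e-11, atol=1e-13,
                        dense_output=True)
        oracle = sol.sol(tau.t)[0]
        assert np.max(np.abs(theta.values - oracle)) < 1e-6

    def test_unstable_parameterization_flagged(self):
        spec = AdmittanceSpec(k_sim=0.0, b_sim=0.0, i_sim=0.01)
        tau = TimeSeries(np.full(int(30 * FS), 50.0), fs=FS)
        with pytest.raises(DivergenceError):
            simulate_admittance(spec, tau)


class TestStiffnessEstimation:
    def test_compliant_setting_recovered(self):
        est = estimate_simulated_stiffness(AdmittanceSpec(k_sim=50.0), (10.0,))
        assert est == pytest.approx(50.0, rel=1e-4)

    def test_stiff_setting_error_below_reported_worst_case(self):
        est = estimate_simulated_stiffness(AdmittanceSpec(k_sim=2000.0), (50, 100, 200))
        assert abs(est - 2000.0) / 2000.0 * 100.0 <= 4.3

    def test_estimate_invariant_to_torque_scaling(self):
        spec = AdmittanceSpec(k_sim=300.0)
        e1 = estimate_simulated_stiffness(spec, (20.0, 40.0))
        e2 = estimate_simulated_stiffness(spec, (40.0, 80.0))
        assert e2 == pytest.approx(e1, rel=1e-9)

    def test_error_does_not_grow_as_integration_step_shrinks(self):
        # the steady state is an exact fixed point of the RK4 map, so the
        # estimation error sits at the numerical floor for every stable step
        spec = AdmittanceSpec(k_sim=2000.0)
        errs = [
            abs(estimate_simulated_stiffness(spec, (100.0,), fs=fs) - 2000.0) / 2000.0
            for fs in (500.0, 2000.0, 8000.0)
        ]
        assert all(e < 1e-8 for e in errs)
        assert errs[-1] <= errs[0] + 1e-12


class TestSinusoidCommand:
    def test_quarter_period_amplitude(self):
        ts = sinusoid_command(1.0, 1.0, 0.0, FS, 1.0)
        i = int(0.25 * FS)
        assert ts.values[i] == pytest.approx(1.0, rel=1e-9)

    def test_zero_amplitude_is_identically_zero(self):
        ts = sinusoid_command(0.0, 1.0, 30.0, FS, 1.0)
        np.testing.assert_allclose(ts.values, 0.0)

    def test_pair_offset_is_a_quarter_period(self):
        freq = 1.0
        left, right = sinusoid_pair(1.0, freq, FS, 4.0)
        # circular cross-correlation over whole periods peaks at f^-1/4
        l = left.values[:-1]  # 8000 samples = 4 whole periods
        r = right.values[:-1]
        xc = np.fft.irfft(np.fft.rfft(l) * np.conj(np.fft.rfft(r)))
        lag = int(np.argmax(xc))
        lag = min(lag, l.size - lag)  # fold to the nearest shift
        assert lag / FS == pytest.approx(1.0 / freq / 4.0, rel=1e-6)

    def test_rom_limit_enforced(self):
        with pytest.raises(InvalidParameterError):
            sinusoid_command(20.0, 1.0, 0.0, FS, 1.0)
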