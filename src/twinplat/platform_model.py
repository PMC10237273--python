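"""Commanded platform motions and the admittance-rendered environment.

Covers the platform-side building blocks: minimum-jerk ramp-and-hold
perturbations, sinusoidal oscillation commands (with the left/right 90°
phase offset used in the oscillatory balance protocol), a fixed-step
simulator of the admittance-controlled mechanical environment
(``I θ̈ + B θ̇ + K θ = τ``), the stiffness-validation estimator
(steady-state torque over displacement), and the position-control
accuracy metrics (phase difference and steady-state error of a measured
ramp against the ideal one).

Range-of-motion limits (±15° DP, ±10° IE) and the 100 °/s perturbation
speed cap are enforced at spec validation: a command that would exceed
them raises rather than silently clipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DivergenceError,
    InvalidParameterError,
    MetricUndefinedError,
)
from .signals import TimeSeries
from .units import deg2rad

__all__ = [
    "PerturbationSpec",
    "AdmittanceSpec",
    "ROM_LIMITS_DEG",
    "SPEED_CAP_DEG_S",
    "minimum_jerk_ramp",
    "minimum_jerk_velocity",
    "ramp_tracking_metrics",
    "simulate_admittance",
    "estimate_simulated_stiffness",
    "stiffness_validation_table",
    "sinusoid_command",
    "sinusoid_pair",
]

#: range-of-motion limits per axis (deg)
ROM_LIMITS_DEG = {"DP": 15.0, "IE": 10.0}
#: rotational perturbation speed cap (deg/s)
SPEED_CAP_DEG_S = 100.0
#: peak velocity of the minimum-jerk quintic is 1.875 * A / T
MIN_JERK_PEAK_FACTOR = 1.875


@dataclass(frozen=True)
class PerturbationSpec:
    """Minimum-jerk ramp-and-hold perturbation.

    ``sign=+1`` follows the protocol convention: DP perturbations
    dorsiflex the foot, IE perturbations evert it.
    """

    amplitude_deg: float = 3.0
    duration_s: float = 0.125
    direction: str = "DP"
    sign: int = 1
    hold_s: float = 0.3

    def __post_init__(self):
        if self.direction not in ROM_LIMITS_DEG:
            raise InvalidParameterError(f"direction must be DP or IE, got {self.direction}")
        if self.amplitude_deg <= 0 or self.duration_s <= 0 or self.hold_s < 0:
            raise InvalidParameterError("amplitude and duration must be positive")
        if self.sign not in (-1, 1):
            raise InvalidParameterError("sign must be +1 or -1")
        if self.amplitude_deg > ROM_LIMITS_DEG[self.direction]:
            raise InvalidParameterError(
                f"amplitude {self.amplitude_deg}° exceeds the "
                f"±{ROM_LIMITS_DEG[self.direction]}° {self.direction} range of motion"
            )
        if self.peak_velocity_deg_s > SPEED_CAP_DEG_S:
            raise InvalidParameterError(
                f"peak velocity {self.peak_velocity_deg_s:.1f} °/s exceeds the "
                f"{SPEED_CAP_DEG_S} °/s cap"
            )

    @property
    def peak_velocity_deg_s(self) -> float:
        """Closed-form peak velocity of the quintic: 1.875·A/T."""
        return MIN_JERK_PEAK_FACTOR * self.amplitude_deg / self.duration_s


@dataclass(frozen=True)
class AdmittanceSpec:
    """Virtual mechanical environment rendered by the admittance controller.

    The controllers' virtual damping/inertia are not protocol quantities;
    defaults are critical damping ``B = 2√(K·I)`` with ``I = 0.1 kg·m²``
    so commanded stiffness settles quickly without overshoot.
    """

    k_sim: float
    b_sim: float | None = None
    i_sim: float = 0.1

    def __post_init__(self):
        if self.k_sim < 0:
            raise InvalidParameterError("k_sim must be >= 0")
        if self.i_sim <= 0:
            raise InvalidParameterError("i_sim must be > 0")
        if self.b_sim is None:
            object.__setattr__(self, "b_sim", 2.0 * np.sqrt(self.k_sim * self.i_sim))
        elif self.b_sim < 0:
            raise InvalidParameterError("b_sim must be >= 0")


def _quintic(s: np.ndarray) -> np.ndarray:
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def minimum_jerk_ramp(spec: PerturbationSpec, fs: float) -> TimeSeries:
    """Minimum-jerk position ramp θ(t)=A(10s³−15s⁴+6s⁵), then hold at A.

    Zero velocity and acceleration at both ends of the ramp; units deg.
    """
    if fs * spec.duration_s < 10:
        raise InvalidParameterError(
            f"fs·duration = {fs * spec.duration_s:.1f} < 10 samples; ramp under-resolved"
        )
    n = int(round((spec.duration_s + spec.hold_s) * fs)) + 1
    t = np.arange(n) / fs
    s = np.clip(t / spec.duration_s, 0.0, 1.0)
    theta = spec.sign * spec.amplitude_deg * _quintic(s)
    return TimeSeries(theta, fs=fs, t0=0.0, units="deg")


def minimum_jerk_velocity(spec: PerturbationSpec, t: np.ndarray) -> np.ndarray:
    """Analytic velocity (deg/s) of the ramp at times ``t`` (0 after T)."""
    t = np.asarray(t, dtype=float)
    s = t / spec.duration_s
    inside = (s >= 0) & (s <= 1)
    v = np.where(
        inside,
        spec.sign * spec.amplitude_deg / spec.duration_s * (30 * s**2 - 60 * s**3 + 30 * s**4),
        0.0,
    )
    return v


def _first_upward_crossing(ts: TimeSeries, level: float) -> float:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    v = ts.values
    if v[0] >= level:
        return ts.t0
    idx = np.flatnonzero((v[:-1] < level) & (v[1:] >= level))
    if idx.size == 0:
        raise MetricUndefinedError(f"series never reaches {level}")
    i = idx[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return ts.t0 + (i + frac) / ts.fs


def ramp_tracking_metrics(
    measured: TimeSeries,
    ideal: TimeSeries,
    levels_deg: np.ndarray | None = None,
    align_level_deg: float = 0.01,
    steady_window_s: tuple[float, float] = (0.15, 0.25),
) -> tuple[float, float]:
    """Position-control accuracy of a measured ramp vs the ideal one.

    Time zero is set where the *ideal* trajectory departs (its
    ``align_level_deg`` crossing) and the same shift is applied to both
    series, so a pure transport delay in the measured response shows up
    in the phase metric.  ``phase_diff`` is the mean, over 26 evenly
    spaced threshold levels from 0.25° to 2.75°, of the measured-minus-
    ideal crossing time (linear interpolation between samples).
    ``steady_state_error`` is the mean absolute angle difference over the
    aligned window 0.15–0.25 s (just after the ideal ramp ends).

    Raises :class:`MetricUndefinedError` if the measured trajectory never
    reaches the top threshold level.
    """
    if levels_deg is None:
        levels_deg = np.linspace(0.25, 2.75, 26)
    shift = _first_upward_crossing(ideal, align_level_deg)
    meas = measured.shifted(-shift)
    idl = ideal.shifted(-shift)
    diffs = [
        _first_upward_crossing(meas, lv) - _first_upward_crossing(idl, lv)
        for lv in levels_deg
    ]
    phase_diff = float(np.mean(diffs))

    t_lo, t_hi = steady_window_s
    window = idl.slice_time(t_lo, t_hi)
    meas_on_grid = np.interp(window.t, meas.t, meas.values)
    steady_state_error = float(np.mean(np.abs(meas_on_grid - window.values)))
    return phase_diff, steady_state_error


def simulate_admittance(
    spec: AdmittanceSpec,
    applied_torque: TimeSeries,
    theta0: float = 0.0,
    omega0: float = 0.0,
) -> TimeSeries:
    """Integrate the rendered environment ``I θ̈ + B θ̇ + K θ = τ(t)``.

    Classical fixed-step RK4 on the torque's own grid, starting from rest
    by default.  For constant τ and K>0 the steady state is τ/K (an exact
    fixed point of the RK4 map).  Output in radians.

    Raises :class:`DivergenceError` if |θ| exceeds 10³ rad (unstable
    parameterization, e.g. K=B=0 with sustained torque).
    """
    tau = applied_torque.values
    n = tau.size
    h = 1.0 / applied_torque.fs
    inv_i = 1.0 / spec.i_sim
    k, b = spec.k_sim, spec.b_sim
    theta = np.empty(n)
    th, om = float(theta0), float(omega0)
    theta[0] = th

    def acc(th_, om_, tau_):
        return (tau_ - b * om_ - k * th_) * inv_i

    for i in range(n - 1):
        t1, t2 = tau[i], tau[i + 1]
        tm = 0.5 * (t1 + t2)
        k1t = om
        k1o = acc(th, om, t1)
        k2t = om + 0.5 * h * k1o
        k2o = acc(th + 0.5 * h * k1t, om + 0.5 * h * k1o, tm)
        k3t = om + 0.5 * h * k2o
        k3o = acc(th + 0.5 * h * k2t, om + 0.5 * h * k2o, tm)
        k4t = om + h * k3o
        k4o = acc(th + h * k3t, om + h * k3o, t2)
        th += h / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t)
        om += h / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o)
        if abs(th) > 1e3:
            raise DivergenceError(
                f"admittance simulation diverged at t={applied_torque.t0 + i * h:.3f} s "
                f"(K={k}, B={b}, I={spec.i_sim})"
            )
        theta[i + 1] = th
    return applied_torque.with_values(theta, units="rad")


def _settle_duration(spec: AdmittanceSpec) -> float:
    wn = np.sqrt(spec.k_sim / spec.i_sim)
    zeta = spec.b_sim / (2.0 * np.sqrt(spec.k_sim * spec.i_sim))
    # ~10 time constants of the dominant pole, floored for slow systems
    return float(max(1.0, 10.0 / max(zeta * wn, 1e-3)))


def estimate_simulated_stiffness(
    spec: AdmittanceSpec,
    test_torques: Sequence[float] = (50.0, 100.0, 200.0),
    fs: float = 2000.0,
) -> float:
    """Estimate rendered stiffness as measured torque over displacement.

    Mirrors the stiffness-validation procedure: for each constant test
    torque, drive the rendered environment to steady state and divide the
    torque by the steady-state rotation; the estimate is the mean over
    test torques (Nm/rad).
    """
    torques = [t for t in test_torques if t != 0.0]
    if not torques:
        raise InvalidParameterError("need at least one nonzero test torque")
    if spec.k_sim <= 0:
        raise InvalidParameterError("stiffness estimation requires k_sim > 0")
    duration = _settle_duration(spec)
    n = int(round(duration * fs)) + 1
    estimates = []
    for tau0 in torques:
        tau = TimeSeries(np.full(n, float(tau0)), fs=fs, units="Nm")
        theta = simulate_admittance(spec, tau)
        tail = theta.values[-max(int(0.1 * fs), 10):]
        theta_ss = float(np.mean(tail))
        if theta_ss == 0.0:
            raise DivergenceError("zero steady-state displacement; cannot estimate stiffness")
        estimates.append(tau0 / theta_ss)
    return float(np.mean(estimates))


def stiffness_validation_table(
    commanded: Sequence[float] = (50.0, 100.0, 250.0, 500.0, 1000.0, 2000.0),
    test_torques: Sequence[float] = (50.0, 100.0, 200.0),
    fs: float = 2000.0,
) -> list[dict]:
    """Commanded-vs-estimated stiffness across the validated range.

    Returns one record per commanded value with the estimate and the
    relative error in percent (the validation-table structure).
    """
    rows = []
    for k in commanded:
        # keep test torques within a plausible deflection for soft settings
        scale = min(1.0, k / 500.0)
        torques = [max(t * scale, 5.0) for t in test_torques]
        est = estimate_simulated_stiffness(AdmittanceSpec(k_sim=k), torques, fs=fs)
        rows.append(
            {
                "commanded_nm_per_rad": float(k),
                "estimated_nm_per_rad": est,
                "relative_error_pct": abs(est - k) / k * 100.0,
            }
        )
    return rows


def sinusoid_command(
    amplitude_deg: float,
    frequency_hz: float,
    phase_deg: float,
    fs: float,
    duration_s: float,
    direction: str = "DP",
) -> TimeSeries:
    """Sinusoidal platform command θ(t) = A·sin(2πft + φ), deg."""
    if frequency_hz >= fs / 2:
        raise InvalidParameterError("frequency must be below Nyquist")
    if amplitude_deg < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    if amplitude_deg > ROM_LIMITS_DEG[direction]:
        raise InvalidParameterError(
            f"amplitude {amplitude_deg}° exceeds the ±{ROM_LIMITS_DEG[direction]}° "
            f"{direction} range of motion"
        )
    n = int(round(duration_s * fs)) + 1
    t = np.arange(n) / fs
    theta = amplitude_deg * np.sin(2 * np.pi * frequency_hz * t + deg2rad(phase_deg))
    return TimeSeries(theta, fs=fs, t0=0.0, units="deg")


def sinusoid_pair(
    amplitude_deg: float,
    frequency_hz: float,
    fs: float,
    duration_s: float,
    phase_offset_deg: float = 90.0,
    direction: str = "DP",
) -> tuple[TimeSeries, TimeSeries]:
    """Left/right platform commands with the configured phase offset.

    The oscillatory balance protocol keeps a 90° offset between the two
    platforms so they never move in the same direction.
    """
    left = sinusoid_command(amplitude_deg, frequency_hz, 0.0, fs, duration_s, direction)
    right = sinusoid_command(
        amplitude_deg, frequency_hz, phase_offset_deg, fs, duration_s, direction
    )
    return left, right
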