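"""Synthetic platform-and-subject generator with known ground truth.

Every input the analysis pipelines need can be generated here at desk
scale: dual-plate quiet standing with stochastic CoP sway and bodyweight
sharing, trigger-gated standing perturbation trials, walking stance-phase
trials at a 100 bpm cadence with catch trials, and unloaded-platform
ramp trials for platform-dynamics identification.

Modelling choices (none of these are measured properties of the real
hardware; they are the minimal structures that make the pipelines
testable):

* **Sway** is a mean-reverting stochastic process per axis per foot: a
  white-noise-driven damped second-order system
  ``ẍ + 2ζω ẋ + ω² x = w(t)``, parameterized directly by its stationary
  SD (the drive intensity follows from the closed form
  ``var(x) = S₀/(4ζω³)``).  Unlike a first-order mean-reverting process
  it has finite path velocity, so the CoP path length (TOTEX) is
  well-defined at any sampling rate.
* **Compliant-surface coupling** is open loop: the sway-driven moment
  (vertical load × CoP lever) rotates the admittance-rendered platform,
  and the rotation adds a CoP shift through a centre-of-mass-height
  lever.  Softer rendered surfaces therefore amplify sway, without
  modelling an active balance controller (a closed static loop would be
  unstable at the compliant settings, which is exactly why real standing
  needs neural control).
* **The 8-channel split** of a target (CoP, load, torque) state is
  underdetermined; the minimum-norm solution for the corner normals and a
  symmetric split of the shear torque residual are fixed so generation is
  deterministic and exactly invertible by the forward reconstruction.
* **Ankle torque** responds to imposed rotation through the subject's
  per-side per-direction (K, B, I), with derivatives taken by the same
  five-point stencil the pipeline uses, so the noiseless round trip is
  exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as _sps

from .errors import (
    GenerationError,
    InfeasibleTargetError,
    InvalidParameterError,
)
from .forceplate import ForcePlateSeries, PlateGeometry
from .impedance import PlatformDynamics, TrialRecord
from .platform_model import AdmittanceSpec, PerturbationSpec, minimum_jerk_ramp
from .signals import TimeSeries, five_point_derivative
from .units import G, cm2m, deg2rad

__all__ = [
    "ImpedanceTriple",
    "SwayParams",
    "SubjectModel",
    "NoiseModel",
    "StandingRecord",
    "default_geometry",
    "default_subject",
    "default_platform_dynamics",
    "decompose_forces_to_channels",
    "synth_standing",
    "standing_perturbation_trials",
    "synth_walking_stance",
    "synth_unloaded_platform_trials",
]

DEFAULT_FS = 2000.0


def default_geometry() -> PlateGeometry:
    """Plausible lever arms (m) for a ~0.5 m force plate; config overrides."""
    return PlateGeometry(a=0.14, b=0.14, c=0.105, d=0.09)


def default_platform_dynamics() -> PlatformDynamics:
    """Ground-truth platform dynamics: rigid, inertia-dominated."""
    return PlatformDynamics(k_p=0.3, b_p=0.05, i_p=0.4)


@dataclass(frozen=True)
class ImpedanceTriple:
    """Ground-truth ankle stiffness/damping/inertia."""

    k: float  # Nm/rad
    b: float  # Nms/rad
    i: float  # kg·m²

    def __post_init__(self):
        if self.k < 0 or self.b < 0 or self.i < 0:
            raise InvalidParameterError("impedance parameters must be >= 0")


@dataclass(frozen=True)
class SwayParams:
    """Mean-reverting sway process parameters (one standing posture).

    ``natural_freq_hz``/``damping_ratio`` set the mean-reversion
    dynamics; ``sd_ap_cm``/``sd_ml_cm`` are the stationary CoP SDs per
    axis.  Defaults give a quiet-standing path length of a few tens of
    cm over 60 s on a rigid surface.
    """

    natural_freq_hz: float = 0.3
    damping_ratio: float = 0.7
    sd_ap_cm: float = 0.35
    sd_ml_cm: float = 0.25

    def __post_init__(self):
        if self.natural_freq_hz <= 0 or self.damping_ratio <= 0:
            raise InvalidParameterError("sway dynamics must be positive")
        if self.sd_ap_cm < 0 or self.sd_ml_cm < 0:
            raise InvalidParameterError("sway SDs must be >= 0")


@dataclass(frozen=True)
class SubjectModel:
    """Synthetic subject ground truth.

    ``impedance[side][direction]`` holds the (K, B, I) triples; sides are
    ``non_dominant``/``dominant`` (subjects are modelled right-side
    dominant, so the left foot is the non-dominant one).
    """

    mass_kg: float = 70.0
    impedance: dict = field(default_factory=lambda: {
        "dominant": {"DP": ImpedanceTriple(320.0, 6.0, 0.012),
                     "IE": ImpedanceTriple(60.0, 2.5, 0.010)},
        "non_dominant": {"DP": ImpedanceTriple(260.0, 5.0, 0.012),
                         "IE": ImpedanceTriple(48.0, 2.0, 0.010)},
    })
    sway: SwayParams = field(default_factory=SwayParams)
    weight_sharing: float = 0.5  # fraction of bodyweight on the left foot
    weight_fluctuation_sd: float = 0.01
    placement_ap_bias_cm: float = 1.0
    placement_ap_jitter_cm: float = 0.8
    placement_ml_bias_cm: float = 0.0
    placement_ml_jitter_cm: float = 0.5
    cop_gain_cm_per_rad: float = 100.0  # ~1 m COM-height lever (compliance loop)
    plate_tilt_cop_gain_cm_per_rad: float = 30.0  # direct CoP shift of a tilting plate

    def __post_init__(self):
        if not (0 < self.mass_kg <= 100):
            raise InvalidParameterError("mass must be in (0, 100] kg (design envelope)")
        if not (0 < self.weight_sharing < 1):
            raise InvalidParameterError("weight-sharing fraction must be in (0, 1)")
        for side in ("dominant", "non_dominant"):
            for direction in ("DP", "IE"):
                trip = self.impedance[side][direction]
                if not isinstance(trip, ImpedanceTriple):
                    raise InvalidParameterError("impedance entries must be ImpedanceTriple")

    @property
    def weight_n(self) -> float:
        return self.mass_kg * G

    def side_of_foot(self, foot: str) -> str:
        """Map a physical foot (left/right) to dominance (right dominant)."""
        return {"left": "non_dominant", "right": "dominant"}[foot]


def default_subject() -> SubjectModel:
    return SubjectModel()


@dataclass(frozen=True)
class NoiseModel:
    """Additive measurement noise; identical seeds reproduce datasets."""

    force_sd_n: float = 0.5
    angle_sd_deg: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.force_sd_n < 0 or self.angle_sd_deg < 0:
            raise InvalidParameterError("noise SDs must be >= 0")


NOISELESS = NoiseModel(force_sd_n=0.0, angle_sd_deg=0.0, seed=0)


# ---------------------------------------------------------------------------
# Channel decomposition (inverse of the torque/CoP reconstruction)
# ---------------------------------------------------------------------------


def decompose_forces_to_channels(
    ap_cm,
    ml_cm,
    load_n,
    torque_dp_nm,
    torque_ie_nm,
    geom: PlateGeometry,
) -> dict[str, np.ndarray]:
    """Solve for 8 plate channels that encode a target plate state.

    Targets: CoP (cm, plate frame), total normal load (N), and the total
    DP/IE torques the channels must reconstruct (the *plate-level* torque,
    i.e. ankle torque plus any platform-dynamics torque, before
    compensation).  All arguments broadcast to a common sample shape.

    Corner normals take the minimum-norm solution of the three moment/sum
    constraints; the torque residual not carried by the normal-force
    moments goes symmetrically into the shear pairs through the height
    lever ``d``.  Raises :class:`InfeasibleTargetError` when a target
    needs a negative corner load, or shear-borne torque with ``d = 0``.
    """
    ap_m = cm2m(np.asarray(ap_cm, dtype=float))
    ml_m = cm2m(np.asarray(ml_cm, dtype=float))
    load = np.asarray(load_n, dtype=float)
    tau_dp = np.asarray(torque_dp_nm, dtype=float)
    tau_ie = np.asarray(torque_ie_nm, dtype=float)
    ap_m, ml_m, load, tau_dp, tau_ie = np.broadcast_arrays(
        ap_m, ml_m, load, tau_dp, tau_ie
    )
    if np.any(load <= 0):
        raise InfeasibleTargetError("target load must be positive everywhere")

    m_ap = ap_m * load
    m_ml = ml_m * load
    a_mat = np.array([
        [1.0, 1.0, 1.0, 1.0],
        [geom.a, -geom.b, -geom.b, geom.a],
        [geom.c, geom.c, -geom.c, -geom.c],
    ])
    pinv = np.linalg.pinv(a_mat)  # minimum-norm right inverse (4x3)
    rhs = np.stack([load, m_ap, m_ml])  # (3, ...)
    fn = np.tensordot(pinv, rhs, axes=(1, 0))  # (4, ...)
    if np.any(fn < -1e-9):
        raise InfeasibleTargetError(
            "target CoP/load/torque requires a negative corner load "
            "(CoP outside the feasible footprint or torque too extreme)"
        )
    fn = np.clip(fn, 0.0, None)

    shear_dp = tau_dp - m_ap
    shear_ie = tau_ie - m_ml
    if geom.d == 0.0:
        if np.any(np.abs(shear_dp) > 1e-9) or np.any(np.abs(shear_ie) > 1e-9):
            raise InfeasibleTargetError(
                "with d = 0 the shear channels carry no torque; targets must "
                "put all torque into the normal-force moments"
            )
        zero = np.zeros_like(load)
        fs1 = fs2 = fs3 = fs4 = zero
    else:
        fs1 = fs2 = shear_dp / (2.0 * geom.d)
        fs3 = fs4 = shear_ie / (2.0 * geom.d)
    return {
        "fn1": fn[0], "fn2": fn[1], "fn3": fn[2], "fn4": fn[3],
        "fs1": fs1, "fs2": np.array(fs2, copy=True),
        "fs3": fs3, "fs4": np.array(fs4, copy=True),
    }


# ---------------------------------------------------------------------------
# Stochastic building blocks
# ---------------------------------------------------------------------------


def _sway_process(
    n: int, fs: float, params: SwayParams, sd_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary mean-reverting sway samples (cm), burn-in discarded."""
    if sd_cm == 0.0:
        return np.zeros(n)
    omega = 2 * np.pi * params.natural_freq_hz
    zeta = params.damping_ratio
    # For ẍ + 2ζωẋ + ω²x = w with two-sided PSD S0: var(x) = S0/(4ζω³).
    # Discrete white drive of variance σe² looks like PSD σe²/fs, so the
    # target stationary SD fixes σe = sd·sqrt(4ζω³·fs).
    sigma_e = sd_cm * np.sqrt(4.0 * zeta * omega**3 * fs)
    num, den, _ = _sps.cont2discrete(
        ([1.0], [1.0, 2 * zeta * omega, omega**2]), 1.0 / fs, method="bilinear"
    )
    burn = int(round(6.0 / max(zeta * omega, 1e-3) * fs))
    e = rng.normal(0.0, sigma_e, size=n + burn)
    x = _sps.lfilter(np.atleast_1d(num.squeeze()), den, e)
    return x[burn:]


def _slow_fluctuation(
    n: int, fs: float, sd: float, rng: np.random.Generator, cutoff_hz: float = 0.2
) -> np.ndarray:
    """Slow first-order mean-reverting fluctuation with stationary SD ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    lam = 2 * np.pi * cutoff_hz
    phi = np.exp(-lam / fs)
    sigma_d = sd * np.sqrt(1.0 - phi**2)
    burn = int(round(6.0 / lam * fs))
    e = rng.normal(0.0, sigma_d, size=n + burn)
    x = _sps.lfilter([1.0], [1.0, -phi], e)
    return x[burn:]


def _second_order_response_filter(
    inertia: float, damping: float, stiffness: float, fs: float
):
    """Discrete filter for θ(t) of I θ̈ + B θ̇ + K θ = u(t) (ZOH input)."""
    num, den, _ = _sps.cont2discrete(
        ([1.0], [inertia, damping, stiffness]), 1.0 / fs, method="zoh"
    )
    return np.atleast_1d(num.squeeze()), den


def _impedance_torque(
    triple: ImpedanceTriple, angle_rad: TimeSeries
) -> np.ndarray:
    """K θ + B θ̇ + I θ̈ with the pipeline's own five-point derivatives."""
    dtheta = five_point_derivative(angle_rad)
    ddtheta = five_point_derivative(dtheta)
    return (
        triple.k * angle_rad.values
        + triple.b * dtheta.values
        + triple.i * ddtheta.values
    )


def _snr_noise_sd(response: np.ndarray, snr_db: float) -> float:
    """Noise SD giving the stated SNR against the response RMS."""
    rms = float(np.sqrt(np.mean(response**2)))
    return rms / 10 ** (snr_db / 20.0)


# ---------------------------------------------------------------------------
# Quiet standing / balance recordings
# ---------------------------------------------------------------------------


@dataclass
class StandingRecord:
    """One synthetic dual-plate standing recording with ground truth."""

    left_plate: ForcePlateSeries
    right_plate: ForcePlateSeries
    platform_angles: dict  # {foot: {axis: TimeSeries deg}}
    ground_truth: dict


_AXIS_OF = {"ap": "DP", "ml": "IE"}


def synth_standing(
    subject: SubjectModel,
    noise: NoiseModel = NOISELESS,
    duration_s: float = 60.0,
    admittance: Optional[AdmittanceSpec] = None,
    platform_motion: Optional[dict] = None,
    geometry: Optional[PlateGeometry] = None,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> StandingRecord:
    """Dual-plate standing: sway, load sharing, and plate channels.

    ``admittance`` renders a compliant surface (both plates, both axes at
    the same stiffness); ``platform_motion`` instead imposes commanded
    angles ``{foot: {axis: TimeSeries deg}}`` (the oscillatory protocol).
    Rigid standing is the default.  The plate channels are solved from
    the per-sample (CoP, load, torque) targets, so running them through
    the CoP/torque reconstruction reproduces the ground truth exactly in
    the noiseless case.
    """
    if admittance is not None and platform_motion is not None:
        raise InvalidParameterError("give either admittance or platform_motion, not both")
    geometry = geometry or default_geometry()
    n = int(round(duration_s * fs)) + 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, noise.seed]))

    # smooth (differentiable) share fluctuation: a rough first-order process
    # would leak spurious CoP path length through the inter-plate lever
    share_params = SwayParams(natural_freq_hz=0.15, damping_ratio=0.7,
                              sd_ap_cm=0.0, sd_ml_cm=0.0)
    share_left = subject.weight_sharing + _sway_process(
        n, fs, share_params, subject.weight_fluctuation_sd, rng
    )
    share_left = np.clip(share_left, 0.05, 0.95)
    loads = {
        "left": subject.weight_n * share_left,
        "right": subject.weight_n * (1.0 - share_left),
    }

    plates: dict[str, ForcePlateSeries] = {}
    angles: dict[str, dict[str, TimeSeries]] = {}
    truth_cop: dict[str, dict[str, np.ndarray]] = {}
    for foot in ("left", "right"):
        side = subject.side_of_foot(foot)
        sway = {
            "ap": _sway_process(n, fs, subject.sway, subject.sway.sd_ap_cm, rng),
            "ml": _sway_process(n, fs, subject.sway, subject.sway.sd_ml_cm, rng),
        }
        cop: dict[str, np.ndarray] = {}
        theta_rad: dict[str, np.ndarray] = {}
        for comp in ("ap", "ml"):
            axis = _AXIS_OF[comp]
            trip = subject.impedance[side][axis]
            if platform_motion is not None:
                theta = deg2rad(platform_motion[foot][axis].values)
                if theta.size != n:
                    raise InvalidParameterError("platform_motion length must match duration")
            elif admittance is not None:
                moment = loads[foot] * cm2m(sway[comp])
                num, den = _second_order_response_filter(
                    admittance.i_sim, admittance.b_sim + trip.b,
                    admittance.k_sim + trip.k, fs,
                )
                theta = _sps.lfilter(num, den, moment)
                if np.any(np.abs(theta) > 0.5):
                    raise GenerationError(
                        "admittance-rendered platform rotation diverged (>0.5 rad)"
                    )
            else:
                theta = np.zeros(n)
            theta_rad[comp] = theta
            # rotation -> CoP lever: COM height for the compliance loop,
            # plate-tilt pressure shift for commanded oscillation
            gain = (
                subject.cop_gain_cm_per_rad
                if admittance is not None
                else subject.plate_tilt_cop_gain_cm_per_rad
            )
            cop[comp] = sway[comp] + gain * theta
        truth_cop[foot] = cop

        torques = {}
        for comp in ("ap", "ml"):
            axis = _AXIS_OF[comp]
            trip = subject.impedance[side][axis]
            theta_ts = TimeSeries(theta_rad[comp], fs=fs, units="rad")
            torques[axis] = (
                _impedance_torque(trip, theta_ts) + loads[foot] * cm2m(cop[comp])
            )

        channels = decompose_forces_to_channels(
            cop["ap"], cop["ml"], loads[foot], torques["DP"], torques["IE"], geometry
        )
        if noise.force_sd_n > 0:
            channels = {
                k: v + rng.normal(0.0, noise.force_sd_n, size=n)
                for k, v in channels.items()
            }
        plates[foot] = ForcePlateSeries.from_arrays(fs=fs, **channels)
        angles[foot] = {}
        for comp in ("ap", "ml"):
            axis = _AXIS_OF[comp]
            deg = np.rad2deg(theta_rad[comp])
            if noise.angle_sd_deg > 0:
                deg = deg + rng.normal(0.0, noise.angle_sd_deg, size=n)
            angles[foot][axis] = TimeSeries(deg, fs=fs, units="deg")

    return StandingRecord(
        left_plate=plates["left"],
        right_plate=plates["right"],
        platform_angles=angles,
        ground_truth={
            "cop_cm": truth_cop,
            "load_n": loads,
            "share_left": share_left,
            "sway_sd_cm": {"ap": subject.sway.sd_ap_cm, "ml": subject.sway.sd_ml_cm},
        },
    )


# ---------------------------------------------------------------------------
# Standing perturbation trials (trigger-gated ramp-and-hold)
# ---------------------------------------------------------------------------


def standing_perturbation_trials(
    subject: SubjectModel,
    side: str,
    direction: str,
    n_trials: int = 30,
    seed: int = 0,
    geometry: Optional[PlateGeometry] = None,
    platform_dynamics: Optional[PlatformDynamics] = None,
    spec: Optional[PerturbationSpec] = None,
    noise: Optional[NoiseModel] = None,
    snr_db: Optional[float] = None,
    fs: float = DEFAULT_FS,
) -> tuple[list[TrialRecord], PlatformDynamics]:
    """Trigger-gated standing ramp-and-hold trials for one side/direction.

    Each trial holds quiet standing until the trigger gate (CoP radius +
    half-bodyweight band, 0.5 s dwell, random 0–0.5 s delay) fires, then
    applies the minimum-jerk ramp.  The plate channels encode the ankle
    response *plus* the platform's own dynamic torque, which the pipeline
    must compensate — the ground-truth :class:`PlatformDynamics` is
    returned alongside.  ``snr_db`` sets the torque-channel noise relative
    to the RMS of the perturbation torque response over the fit window
    (overrides ``noise.force_sd_n`` routing).
    """
    from .impedance import standing_trigger_gate  # local import, avoids cycle

    geometry = geometry or default_geometry()
    platform_dynamics = platform_dynamics or default_platform_dynamics()
    spec = spec or PerturbationSpec(direction=direction)
    noise = noise if noise is not None else NOISELESS
    trip = subject.impedance[side][direction]
    half_bw = subject.weight_n / 2.0

    pre_s, post_s = 1.1, 0.6
    n = int(round((pre_s + post_s) * fs)) + 1
    nominal_cop = (1.0, 0.0)
    seeds = np.random.SeedSequence(seed).spawn(n_trials)
    trials: list[TrialRecord] = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        trial_seed = int(seq.generate_state(1)[0] % (2**31))
        cop_ap = nominal_cop[0] + _sway_process(
            n, fs, subject.sway, min(subject.sway.sd_ap_cm, 0.12), rng
        )
        cop_ml = nominal_cop[1] + _sway_process(
            n, fs, subject.sway, min(subject.sway.sd_ml_cm, 0.12), rng
        )
        load = half_bw + _slow_fluctuation(
            n, fs, subject.weight_fluctuation_sd * subject.weight_n, rng
        )
        cop_ap_ts = TimeSeries(cop_ap, fs=fs, units="cm")
        cop_ml_ts = TimeSeries(cop_ml, fs=fs, units="cm")
        load_ts = TimeSeries(load, fs=fs, units="N")
        onset = standing_trigger_gate(
            cop_ap_ts, cop_ml_ts, nominal_cop, load_ts, half_bw, seed=trial_seed
        )
        if onset is None:
            # conditions never met within this window; fall back to a mid-trial
            # perturbation so the block always completes (flagged in meta)
            onset = pre_s
        onset = round(onset * fs) / fs
        if onset + spec.duration_s + 0.25 > (n - 1) / fs:
            onset = round((pre_s) * fs) / fs

        ramp = minimum_jerk_ramp(spec, fs)
        theta_deg = np.zeros(n)
        i0 = int(round(onset * fs))
        seg = ramp.values[: n - i0]
        theta_deg[i0 : i0 + seg.size] = seg
        theta_deg[i0 + seg.size :] = seg[-1] if seg.size else 0.0
        theta_ts = TimeSeries(deg2rad(theta_deg), fs=fs, units="rad")

        tau_response = _impedance_torque(trip, theta_ts)
        tau_platform = platform_dynamics.torque_for(
            TimeSeries(theta_deg, fs=fs, units="deg")
        ).values
        baseline = load * cm2m(cop_ap if direction == "DP" else cop_ml)
        tau_ankle = tau_response + baseline
        tau_dp_total = (tau_ankle + tau_platform) if direction == "DP" else load * cm2m(cop_ap)
        tau_ie_total = (tau_ankle + tau_platform) if direction == "IE" else load * cm2m(cop_ml)

        channels = decompose_forces_to_channels(
            cop_ap, cop_ml, load, tau_dp_total, tau_ie_total, geometry
        )
        force_sd = noise.force_sd_n
        if snr_db is not None:
            i_win = slice(i0, i0 + int(round(0.1 * fs)) + 1)
            tau_sd = _snr_noise_sd(tau_response[i_win], snr_db)
            # route the torque-level SD through the 8 channels' lever arms
            lever = np.sqrt(
                2 * geometry.a**2 + 2 * geometry.b**2 + 2 * geometry.d**2
            ) if direction == "DP" else np.sqrt(4 * geometry.c**2 + 2 * geometry.d**2)
            force_sd = tau_sd / lever
        if force_sd > 0:
            channels = {
                k: v + rng.normal(0.0, force_sd, size=n) for k, v in channels.items()
            }
        plate = ForcePlateSeries.from_arrays(fs=fs, **channels)

        angle_deg = theta_deg.copy()
        if noise.angle_sd_deg > 0:
            angle_deg = angle_deg + rng.normal(0.0, noise.angle_sd_deg, size=n)
        trials.append(
            TrialRecord(
                side=side,
                direction=direction,
                perturbed=True,
                ankle_angle=TimeSeries(angle_deg, fs=fs, units="deg"),
                platform_angle=TimeSeries(theta_deg, fs=fs, units="deg"),
                plate=plate,
                onset_s=onset,
                meta={"ground_truth": trip, "nominal_cop_cm": nominal_cop},
            )
        )
    return trials, platform_dynamics


# ---------------------------------------------------------------------------
# Walking stance-phase trials
# ---------------------------------------------------------------------------


def _stance_templates(n: int, subject: SubjectModel, direction: str):
    """Smooth stance-phase ankle-angle (deg) and torque (Nm) templates.

    The vertical-force double peak and the heel-strike→toe-off angle
    progression are stylized shapes, not subject data; the torque template
    peaks near terminal stance like a plantarflexion push-off.
    """
    s = np.linspace(0.0, 1.0, n)
    smooth = 3 * s**2 - 2 * s**3
    if direction == "DP":
        angle = -5.0 + 15.0 * smooth
        tau_peak = 0.8 * subject.mass_kg
    else:
        angle = 2.0 * np.sin(np.pi * s)
        tau_peak = 0.12 * subject.mass_kg
    torque = tau_peak * 6.75 * s**2 * (1.0 - s)
    return angle, torque


def synth_walking_stance(
    subject: SubjectModel,
    side: str,
    direction: str,
    n_trials: int = 80,
    perturb_fraction: float = 0.5,
    cadence_bpm: float = 100.0,
    stance_fraction_of_cycle: float = 0.6,
    perturb_at_stance_fraction: float = 0.45,
    stance_jitter: float = 0.02,
    amplitude_variability: float = 0.025,
    wander_fraction: float = 0.01,
    seed: int = 0,
    spec: Optional[PerturbationSpec] = None,
    noise: Optional[NoiseModel] = None,
    snr_db: Optional[float] = None,
    fs: float = DEFAULT_FS,
) -> list[TrialRecord]:
    """Stance-phase trials at the metronome cadence, half perturbed.

    One trial is one step onto the platform.  The stance duration follows
    the cadence (step interval 60/bpm s, stance = 60% of the gait cycle).
    Perturbed trials receive the minimum-jerk ramp at ~45% of stance (±2%
    jitter); catch trials carry the nominal onset so catch subtraction can
    extract windows at matching phase.  Foot-placement offsets are drawn
    with the subject's bias and jitter — some fall outside the acceptance
    windows on purpose, to exercise the rejection rules.  Perturbed/catch
    order is randomized in blocks.
    """
    n_pert = int(round(n_trials * perturb_fraction))
    if 2 * n_pert != n_trials:
        raise InvalidParameterError("n_trials must split evenly into perturbed/catch halves")
    spec = spec or PerturbationSpec(direction=direction)
    noise = noise if noise is not None else NOISELESS
    trip = subject.impedance[side][direction]

    step_s = 60.0 / cadence_bpm
    stance_s = stance_fraction_of_cycle * 2.0 * step_s
    n = int(round(stance_s * fs)) + 1
    base_angle, base_torque = _stance_templates(n, subject, direction)
    nominal_onset = round(perturb_at_stance_fraction * stance_s * fs) / fs

    rng = np.random.default_rng(np.random.SeedSequence([seed, noise.seed]))
    flags = np.array([True] * n_pert + [False] * (n_trials - n_pert))
    rng.shuffle(flags)

    # torque-channel noise SD: either from the stated SNR against the
    # nominal perturbation response over the fit window, or the noise model
    tau_sd = noise.force_sd_n
    if snr_db is not None:
        ramp = minimum_jerk_ramp(spec, fs)
        i0 = int(round(nominal_onset * fs))
        delta = np.zeros(n)
        seg = ramp.values[: n - i0]
        delta[i0 : i0 + seg.size] = seg
        delta[i0 + seg.size :] = seg[-1] if seg.size else 0.0
        response = _impedance_torque(trip, TimeSeries(deg2rad(delta), fs=fs, units="rad"))
        i_win = slice(i0, i0 + int(round(0.1 * fs)) + 1)
        tau_sd = _snr_noise_sd(response[i_win], snr_db)

    trials: list[TrialRecord] = []
    for perturbed in flags:
        scale = rng.normal(1.0, amplitude_variability) if amplitude_variability else 1.0
        wander = _slow_fluctuation(
            n, fs, wander_fraction * max(float(np.abs(base_torque).max()), 1.0),
            rng, cutoff_hz=1.0,
        )
        torque = scale * base_torque + wander
        angle = scale * base_angle
        platform = np.zeros(n)
        onset = nominal_onset
        if perturbed:
            onset = (
                perturb_at_stance_fraction
                + rng.uniform(-stance_jitter, stance_jitter)
            ) * stance_s
            onset = round(onset * fs) / fs
            ramp = minimum_jerk_ramp(spec, fs)
            i0 = int(round(onset * fs))
            seg = ramp.values[: n - i0]
            delta = np.zeros(n)
            delta[i0 : i0 + seg.size] = seg
            delta[i0 + seg.size :] = seg[-1] if seg.size else 0.0
            platform = delta
            angle = angle + delta
            delta_ts = TimeSeries(deg2rad(delta), fs=fs, units="rad")
            response = _impedance_torque(trip, delta_ts)
            torque = torque + response
        if tau_sd:
            torque = torque + rng.normal(0.0, tau_sd, size=n)
        if noise.angle_sd_deg > 0:
            angle = angle + rng.normal(0.0, noise.angle_sd_deg, size=n)

        trials.append(
            TrialRecord(
                side=side,
                direction=direction,
                perturbed=bool(perturbed),
                ankle_angle=TimeSeries(angle, fs=fs, units="deg"),
                platform_angle=TimeSeries(platform, fs=fs, units="deg"),
                torque=TimeSeries(torque, fs=fs, units="Nm"),
                placement_ap_cm=float(rng.normal(subject.placement_ap_bias_cm,
                                                 subject.placement_ap_jitter_cm)),
                placement_ml_cm=float(rng.normal(subject.placement_ml_bias_cm,
                                                 subject.placement_ml_jitter_cm)),
                onset_s=float(onset),
                meta={
                    "ground_truth": trip,
                    "heel_strike_s": 0.0,
                    "toe_off_s": stance_s,
                    "cadence_bpm": cadence_bpm,
                },
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Unloaded platform trials (for platform-dynamics identification)
# ---------------------------------------------------------------------------


def synth_unloaded_platform_trials(
    platform: Optional[PlatformDynamics] = None,
    n_trials: int = 5,
    spec: Optional[PerturbationSpec] = None,
    torque_noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = DEFAULT_FS,
) -> list[TrialRecord]:
    """Ramp-and-hold trials on an empty platform (torque = platform dynamics)."""
    platform = platform or default_platform_dynamics()
    spec = spec or PerturbationSpec()
    rng = np.random.default_rng(seed)
    pre = int(round(0.1 * fs))
    ramp = minimum_jerk_ramp(spec, fs)
    theta_deg = np.concatenate([np.zeros(pre), ramp.values])
    angle_ts = TimeSeries(theta_deg, fs=fs, units="deg")
    tau_clean = platform.torque_for(angle_ts).values
    trials = []
    for _ in range(n_trials):
        tau = tau_clean.copy()
        if torque_noise_sd > 0:
            tau = tau + rng.normal(0.0, torque_noise_sd, size=tau.size)
        trials.append(
            TrialRecord(
                side="n/a",
                direction=spec.direction,
                perturbed=True,
                ankle_angle=angle_ts,
                platform_angle=angle_ts,
                torque=TimeSeries(tau, fs=fs, units="Nm"),
                onset_s=pre / fs,
            )
        )
    return trials
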