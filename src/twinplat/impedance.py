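"""Ankle impedance identification from ramp-and-hold perturbation trials.

The ankle is modelled over a short (100 ms) post-perturbation window as a
second-order linear time-invariant system

.. math::

    \\Delta\\tau(t) = K\\,\\Delta\\theta(t) + B\\,\\Delta\\dot\\theta(t)
                      + I\\,\\Delta\\ddot\\theta(t)

where Δθ and Δτ are *differential* signals: the perturbed responses with
the unperturbed behaviour removed (standing: the value at perturbation
onset; walking: the averaged catch-trial trajectory, with each trial
shifted so the difference at onset is zero).  K, B, I are found by
non-negativity-constrained least squares and the fit quality is scored as
the percentage of variance accounted for,

.. math::

    \\%VAF = 100\\,(1 - \\mathrm{var}(\\Delta\\tau - \\Delta\\hat\\tau)
                       / \\mathrm{var}(\\Delta\\tau)).

The module also covers the surrounding protocol machinery: platform
dynamics identification (so the moving plate's own torque can be
subtracted), the standing trigger gate (CoP-radius + half-bodyweight
dwell), the walking trial screening rules (foot-placement windows and the
3-SD trajectory rule), and the end-to-end standing/walking protocols run
against the synthetic subject generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import (
    EmptyAcceptError,
    FitError,
    IdentificationError,
    InsufficientDataError,
    UndefinedRatioError,
)
from .forceplate import ForcePlateSeries, PlateGeometry, ankle_torques
from .signals import TimeSeries, five_point_derivative, lowpass_filter
from .units import G, deg2rad

__all__ = [
    "TrialRecord",
    "ImpedanceFit",
    "PlatformDynamics",
    "DifferentialSignals",
    "identify_platform_dynamics",
    "standing_trigger_gate",
    "walking_trial_filter",
    "build_differential_signals",
    "fit_second_order_impedance",
    "symmetry_ratio",
    "standing_fit_from_trials",
    "walking_fit_from_trials",
    "run_standing_impedance",
    "run_walking_impedance",
    "SIDES",
    "DIRECTIONS",
]

SIDES = ("non_dominant", "dominant")
DIRECTIONS = ("DP", "IE")

#: differential-signal window after perturbation onset (s)
FIT_WINDOW_S = 0.100
#: low-pass cutoff applied to angles and forces before any differentiation (Hz)
FILTER_CUTOFF_HZ = 15.0
FILTER_ORDER = 4


@dataclass
class TrialRecord:
    """One perturbation (or catch) trial.

    ``ankle_angle``/``platform_angle`` in deg, ``torque`` in Nm (ankle
    level unless ``plate`` is present, in which case the pipeline
    reconstructs torque from the 8 plate channels).  ``onset_s`` is the
    perturbation onset; catch trials carry the *nominal* onset so windows
    can be extracted at matching phase.
    """

    side: str
    direction: str
    perturbed: bool
    ankle_angle: TimeSeries
    platform_angle: TimeSeries
    torque: Optional[TimeSeries] = None
    plate: Optional[ForcePlateSeries] = None
    placement_ap_cm: float = 0.0
    placement_ml_cm: float = 0.0
    onset_s: Optional[float] = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ImpedanceFit:
    """Constrained second-order impedance estimate with fit quality."""

    k: float  # stiffness, Nm/rad
    b: float  # damping, Nms/rad
    i: float  # inertia, kg·m²
    vaf: float  # % variance accounted for (clipped to [0, 100])
    n_trials_used: int = 0

    def as_dict(self) -> dict:
        return {
            "k": self.k, "b": self.b, "i": self.i,
            "vaf": self.vaf, "n_trials_used": self.n_trials_used,
        }


@dataclass(frozen=True)
class PlatformDynamics:
    """The platform's own second-order dynamics along one axis.

    ``inertia_dominance`` is the fraction of the dynamic-torque variance
    carried by the I·θ̈ term; a rigid platform is inertia-dominated.
    """

    k_p: float
    b_p: float
    i_p: float
    inertia_dominance: float = float("nan")

    def torque_for(self, platform_angle_deg: TimeSeries) -> TimeSeries:
        """Platform-induced torque (Nm) for a measured platform angle."""
        theta = platform_angle_deg.with_values(
            deg2rad(platform_angle_deg.values), units="rad"
        )
        dtheta = five_point_derivative(theta)
        ddtheta = five_point_derivative(dtheta)
        tau = self.k_p * theta.values + self.b_p * dtheta.values + self.i_p * ddtheta.values
        return platform_angle_deg.with_values(tau, units="Nm")


@dataclass(frozen=True)
class DifferentialSignals:
    """Averaged differential trajectories over the fit window (radians)."""

    dtheta: TimeSeries  # rad
    dtheta_dot: TimeSeries  # rad/s
    dtheta_ddot: TimeSeries  # rad/s²
    dtau: TimeSeries  # Nm
    n_trials: int


def _angle_kinematics_rad(angle_deg: TimeSeries):
    theta = angle_deg.with_values(deg2rad(angle_deg.values), units="rad")
    dtheta = five_point_derivative(theta)
    ddtheta = five_point_derivative(dtheta)
    return theta, dtheta, ddtheta


def identify_platform_dynamics(unloaded_trials: Sequence[TrialRecord]) -> PlatformDynamics:
    """Identify the platform's K/B/I from unloaded ramp-and-hold trials.

    Regresses measured torque on [θ, θ̇, θ̈] (ordinary least squares —
    the platform parameters are not sign-constrained a priori, though a
    physical plate yields non-negative ones).  ``inertia_dominance`` is
    the variance share of the inertial term among the three model terms.
    """
    if not unloaded_trials:
        raise IdentificationError("no unloaded trials provided")
    cols, taus = [], []
    for tr in unloaded_trials:
        if tr.torque is None:
            raise IdentificationError("unloaded trials must carry measured torque")
        theta, dtheta, ddtheta = _angle_kinematics_rad(tr.platform_angle)
        cols.append(np.column_stack([theta.values, dtheta.values, ddtheta.values]))
        taus.append(tr.torque.values)
    x = np.vstack(cols)
    y = np.concatenate(taus)
    if np.allclose(y, 0.0):
        return PlatformDynamics(0.0, 0.0, 0.0, inertia_dominance=float("nan"))
    if np.linalg.matrix_rank(x) < 3:
        raise IdentificationError("rank-deficient regressors in platform identification")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    k_p, b_p, i_p = (float(v) for v in beta)
    term_vars = np.array([np.var(beta[j] * x[:, j]) for j in range(3)])
    total = term_vars.sum()
    dominance = float(term_vars[2] / total) if total > 0 else float("nan")
    return PlatformDynamics(k_p, b_p, i_p, inertia_dominance=dominance)


def standing_trigger_gate(
    cop_ap: TimeSeries,
    cop_ml: TimeSeries,
    nominal_cop_cm: tuple[float, float],
    load: TimeSeries,
    half_bodyweight_n: float,
    seed: int,
    radius_cm: float = 0.5,
    load_band_kg: float = 2.0,
    dwell_s: float = 0.5,
    max_delay_s: float = 0.5,
) -> Optional[float]:
    """First time the standing trigger conditions have held for 0.5 s.

    Conditions: the plate CoP stays within ``radius_cm`` of the nominal
    CoP *and* the plate load stays within ±``load_band_kg``·g of half the
    subject's bodyweight.  When both have held for ``dwell_s``
    consecutively, a uniform random delay in [0, ``max_delay_s``] s (drawn
    from ``seed``) is added so the subject cannot predict the
    perturbation.  Returns the perturbation onset time, or ``None`` if the
    conditions are never satisfied — a valid outcome, not an error.
    """
    cop_ap.require_same_grid(cop_ml, what="trigger CoP")
    cop_ap.require_same_grid(load, what="trigger load")
    fs = cop_ap.fs
    dist = np.hypot(
        cop_ap.values - nominal_cop_cm[0], cop_ml.values - nominal_cop_cm[1]
    )
    band = load_band_kg * G
    ok = (dist <= radius_cm) & (np.abs(load.values - half_bodyweight_n) <= band)
    n_dwell = int(round(dwell_s * fs)) + 1  # samples spanning exactly dwell_s
    if n_dwell > len(ok):
        return None
    # run length of consecutive satisfied samples ending at each index
    run = np.zeros(len(ok), dtype=int)
    acc = 0
    for i, flag in enumerate(ok):
        acc = acc + 1 if flag else 0
        run[i] = acc
    hits = np.flatnonzero(run >= n_dwell)
    if hits.size == 0:
        return None
    t_dwell_end = cop_ap.t0 + hits[0] / fs
    delay = float(np.random.default_rng(seed).uniform(0.0, max_delay_s))
    return t_dwell_end + delay


def walking_trial_filter(
    trials: Sequence[TrialRecord],
    ap_window_cm: tuple[float, float] = (-0.5, 2.5),
    ml_window_cm: tuple[float, float] = (-1.0, 1.0),
    sd_limit: float = 3.0,
) -> tuple[list[TrialRecord], list[TrialRecord], dict[int, str]]:
    """Screen walking trials by foot placement and trajectory outliers.

    First rejects trials whose foot placement falls outside the closed
    AP/ML windows (cm from the DP/IE rotation axes).  Then, over the
    remaining trials, rejects any whose torque or ankle-angle trajectory
    strays more than ``sd_limit`` standard deviations from the per-sample
    mean at any sample (one pass, no iterative re-screening).  Returns
    (accepted, rejected, reasons-by-input-index).

    Raises :class:`EmptyAcceptError` if nothing survives.
    """
    reasons: dict[int, str] = {}
    placement_ok: list[int] = []
    for idx, tr in enumerate(trials):
        if not (ap_window_cm[0] <= tr.placement_ap_cm <= ap_window_cm[1]):
            reasons[idx] = (
                f"placement AP {tr.placement_ap_cm:+.2f} cm outside "
                f"[{ap_window_cm[0]}, {ap_window_cm[1]}]"
            )
        elif not (ml_window_cm[0] <= tr.placement_ml_cm <= ml_window_cm[1]):
            reasons[idx] = (
                f"placement ML {tr.placement_ml_cm:+.2f} cm outside "
                f"[{ml_window_cm[0]}, {ml_window_cm[1]}]"
            )
        else:
            placement_ok.append(idx)

    survivors = list(placement_ok)
    if len(survivors) >= 2:
        for kind, getter in (
            ("torque", lambda tr: tr.torque.values),
            ("position", lambda tr: tr.ankle_angle.values),
        ):
            mat = np.vstack([getter(trials[i]) for i in survivors])
            mean = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.abs(mat - mean) / sd
            z = np.where(sd > 0, z, 0.0)
            bad_rows = np.flatnonzero(np.any(z > sd_limit, axis=1))
            for row in bad_rows:
                idx = survivors[row]
                if idx not in reasons:
                    reasons[idx] = (
                        f"{kind} trajectory beyond {sd_limit} SD from the per-sample mean"
                    )
        survivors = [i for i in survivors if i not in reasons]

    accepted = [trials[i] for i in survivors]
    rejected = [trials[i] for i in sorted(reasons)]
    if not accepted:
        raise EmptyAcceptError("all trials rejected", reasons=reasons)
    return accepted, rejected, reasons


#: samples of context kept on each side of the fit window so that every
#: retained sample of the twice-applied derivative uses the interior stencil
_DERIV_PAD = 4

#: pre-onset baseline window (s before onset): mean over [onset-0.125, onset-0.075].
#: Referencing the differentials to this baseline instead of the single onset
#: sample keeps them zero at onset (up to noise) while staying clear of the
#: acausal precursor that zero-phase filtering smears ahead of the ramp.
_BASELINE_WINDOW_S = (0.125, 0.075)


def _window_slice(ts: TimeSeries, onset_s: float, window_s: float) -> np.ndarray:
    """Fit-window samples padded by ``_DERIV_PAD`` on each side.

    Index ``_DERIV_PAD`` of the returned segment is the onset sample.
    """
    fs = ts.fs
    i0 = int(round((onset_s - ts.t0) * fs))
    n = int(round(window_s * fs)) + 1
    if i0 - _DERIV_PAD < 0 or i0 + n + _DERIV_PAD > len(ts):
        raise InsufficientDataError(
            f"fit window [{onset_s:.3f}, {onset_s + window_s:.3f}] s (+ derivative "
            "context) extends past the trial"
        )
    return ts.values[i0 - _DERIV_PAD : i0 + n + _DERIV_PAD]


def _baseline(ts: TimeSeries, onset_s: float) -> float:
    """Pre-onset baseline: mean over the 50 ms window ending 75 ms early."""
    fs = ts.fs
    i0 = int(round((onset_s - ts.t0) * fs))
    j0 = i0 - int(round(_BASELINE_WINDOW_S[0] * fs))
    j1 = i0 - int(round(_BASELINE_WINDOW_S[1] * fs))
    if j0 < 0 or j1 <= j0:
        raise InsufficientDataError(
            "trial too short before the onset for baseline referencing"
        )
    return float(np.mean(ts.values[j0:j1]))


def build_differential_signals(
    perturbed: Sequence[TrialRecord],
    catch_mean: Optional[TrialRecord] = None,
    window_s: float = FIT_WINDOW_S,
) -> DifferentialSignals:
    """Averaged differential position/torque over the post-onset window.

    Standing (``catch_mean is None``): perturbed trials are averaged over
    the window starting at each trial's onset, and the averaged
    trajectories are referenced to their onset values, so the difference
    at onset is zero.

    Walking: each perturbed trial has the averaged catch trajectory
    (extracted at the catch record's nominal onset) subtracted, is shifted
    along y so the difference at onset is zero, and the shifted
    differentials are averaged.

    Velocity and acceleration come from the five-point midpoint
    derivative of the averaged differential position.  Angles are
    converted to radians so stiffness is in Nm/rad.
    """
    if not perturbed:
        raise InsufficientDataError("no perturbed trials")
    fs = perturbed[0].ankle_angle.fs
    th_acc, tau_acc = [], []
    if catch_mean is not None:
        if catch_mean.onset_s is None:
            raise InsufficientDataError("catch mean must carry the nominal onset")
        th_catch = _window_slice(catch_mean.ankle_angle, catch_mean.onset_s, window_s)
        tau_catch = _window_slice(catch_mean.torque, catch_mean.onset_s, window_s)
        th_catch_bl = _baseline(catch_mean.ankle_angle, catch_mean.onset_s)
        tau_catch_bl = _baseline(catch_mean.torque, catch_mean.onset_s)
    for tr in perturbed:
        if tr.onset_s is None:
            raise InsufficientDataError("perturbed trial lacks an onset")
        th = _window_slice(tr.ankle_angle, tr.onset_s, window_s)
        tau = _window_slice(tr.torque, tr.onset_s, window_s)
        th_bl = _baseline(tr.ankle_angle, tr.onset_s)
        tau_bl = _baseline(tr.torque, tr.onset_s)
        if catch_mean is not None:
            th = th - th_catch
            tau = tau - tau_catch
            th_bl -= th_catch_bl
            tau_bl -= tau_catch_bl
        # y-shift so the differential is zero at onset (pre-onset baseline)
        th_acc.append(th - th_bl)
        tau_acc.append(tau - tau_bl)
    dtheta_deg = np.mean(th_acc, axis=0)
    dtau = np.mean(tau_acc, axis=0)
    pad = _DERIV_PAD
    dtheta_padded = TimeSeries(deg2rad(dtheta_deg), fs=fs, t0=-pad / fs, units="rad")
    dtheta_dot_p = five_point_derivative(dtheta_padded)
    dtheta_ddot_p = five_point_derivative(dtheta_dot_p)

    def trim(ts: TimeSeries) -> TimeSeries:
        return TimeSeries(ts.values[pad:-pad], fs=fs, t0=0.0, units=ts.units)

    return DifferentialSignals(
        dtheta=trim(dtheta_padded),
        dtheta_dot=trim(dtheta_dot_p),
        dtheta_ddot=trim(dtheta_ddot_p),
        dtau=TimeSeries(dtau[pad:-pad], fs=fs, t0=0.0, units="Nm"),
        n_trials=len(perturbed),
    )


def fit_second_order_impedance(sig: DifferentialSignals) -> ImpedanceFit:
    """Non-negative least-squares fit of (K, B, I) to the differentials.

    Solves ``min ‖Δτ − (KΔθ + BΔθ̇ + IΔθ̈)‖²`` subject to K, B, I ≥ 0 and
    scores %VAF on the residual variance.  A %VAF below zero (model worse
    than the mean) is clipped to 0 with a warning.
    """
    x = np.column_stack([sig.dtheta.values, sig.dtheta_dot.values, sig.dtheta_ddot.values])
    y = sig.dtau.values
    if np.all(np.ptp(x, axis=0) == 0.0):
        raise FitError("degenerate (constant) regressors; cannot identify impedance")
    coef, _ = nnls(x, y)
    resid = y - x @ coef
    var_y = float(np.var(y))
    if var_y == 0.0:
        vaf = 100.0 if np.allclose(resid, 0.0) else 0.0
    else:
        vaf = 100.0 * (1.0 - float(np.var(resid)) / var_y)
    if vaf < 0.0:
        warnings.warn("%VAF below 0 (model worse than the mean); clipped to 0",
                      stacklevel=2)
        vaf = 0.0
    return ImpedanceFit(
        k=float(coef[0]), b=float(coef[1]), i=float(coef[2]),
        vaf=min(vaf, 100.0), n_trials_used=sig.n_trials,
    )


def symmetry_ratio(nd: ImpedanceFit, d: ImpedanceFit) -> float:
    """Non-dominant over dominant stiffness."""
    if d.k <= 0:
        raise UndefinedRatioError("dominant stiffness is zero; symmetry ratio undefined")
    return nd.k / d.k


# ---------------------------------------------------------------------------
# End-to-end protocols against the synthetic subject generator
# ---------------------------------------------------------------------------


def _filter_trial(tr: TrialRecord) -> TrialRecord:
    """Low-pass (15 Hz zero-phase) the trial's kinematic and force data.

    An LTI filter applied to both sides of τ = Kθ + Bθ̇ + Iθ̈ preserves
    the relation, so filtering before differentiation does not bias the
    fit while it suppresses wide-band measurement noise.
    """
    def lp(ts: Optional[TimeSeries]):
        return None if ts is None else lowpass_filter(ts, FILTER_CUTOFF_HZ, FILTER_ORDER)

    return TrialRecord(
        side=tr.side,
        direction=tr.direction,
        perturbed=tr.perturbed,
        ankle_angle=lp(tr.ankle_angle),
        platform_angle=lp(tr.platform_angle),
        torque=lp(tr.torque),
        plate=None if tr.plate is None else tr.plate.map(
            lambda s: lowpass_filter(s, FILTER_CUTOFF_HZ, FILTER_ORDER)
        ),
        placement_ap_cm=tr.placement_ap_cm,
        placement_ml_cm=tr.placement_ml_cm,
        onset_s=tr.onset_s,
        meta=tr.meta,
    )


def _reconstruct_torque(
    tr: TrialRecord, geom: PlateGeometry, platform: Optional[PlatformDynamics]
) -> TrialRecord:
    """Fill ``torque`` from plate channels via the torque reconstruction."""
    if tr.plate is None:
        return tr
    tau_platform = None
    if platform is not None:
        tau_platform = platform.torque_for(tr.platform_angle)
    tau_dp, tau_ie = ankle_torques(tr.plate, geom, tau_platform if tr.direction == "DP" else None,
                                   tau_platform if tr.direction == "IE" else None)
    tr.torque = tau_dp if tr.direction == "DP" else tau_ie
    return tr


def standing_fit_from_trials(
    trials: Sequence[TrialRecord],
    geometry: PlateGeometry,
    platform: Optional[PlatformDynamics],
    lowpass: bool = True,
) -> ImpedanceFit:
    """Standing condition fit: filter, reconstruct torque, fit.

    No standing trials are discarded (the protocol's torque and
    perturbation curves are highly consistent across trials).
    ``lowpass=False`` skips the 15 Hz noise-suppression stage (useful on
    noiseless data, where the zero-phase precursor is the only thing the
    filter would add).
    """
    processed = [
        _reconstruct_torque(_filter_trial(tr) if lowpass else tr, geometry, platform)
        for tr in trials
    ]
    return fit_second_order_impedance(build_differential_signals(processed))


def walking_fit_from_trials(
    trials: Sequence[TrialRecord],
    lowpass: bool = True,
) -> tuple[ImpedanceFit, int]:
    """Walking condition fit: filter, screen, catch-subtract, fit.

    Returns the fit and the number of screened-out trials.
    """
    if lowpass:
        trials = [_filter_trial(tr) for tr in trials]
    perturbed = [tr for tr in trials if tr.perturbed]
    catch = [tr for tr in trials if not tr.perturbed]
    acc_p, rej_p, _ = walking_trial_filter(perturbed)
    acc_c, rej_c, _ = walking_trial_filter(catch)
    catch_mean = _average_trials(acc_c)
    sig = build_differential_signals(acc_p, catch_mean=catch_mean)
    return fit_second_order_impedance(sig), len(rej_p) + len(rej_c)


def run_standing_impedance(
    subject,
    n_trials: int = 30,
    seed: int = 0,
    geometry: Optional[PlateGeometry] = None,
    snr_db: Optional[float] = None,
    noise=None,
    fs: float = 2000.0,
) -> dict:
    """Standing protocol: trigger-gated perturbations, fit per side/direction.

    For each side × direction, ``n_trials`` trigger-gated ramp-and-hold
    perturbations (dorsiflexing for DP, everting for IE) are synthesized
    from the subject's ground truth, ankle torque is reconstructed from
    the 8 plate channels with platform-dynamics compensation, differential
    signals are built over the 100 ms window, and the constrained
    second-order model is fit.  No standing trials are discarded.

    Returns ``{"fits": {(side, direction): ImpedanceFit},
    "symmetry": {direction: ratio}}``.
    """
    from . import synth  # local import to avoid a cycle

    geometry = geometry or synth.default_geometry()
    rng_seeds = np.random.SeedSequence(seed).spawn(len(SIDES) * len(DIRECTIONS))
    fits: dict[tuple[str, str], ImpedanceFit] = {}
    idx = 0
    for side in SIDES:
        for direction in DIRECTIONS:
            sub_seed = int(rng_seeds[idx].generate_state(1)[0] % (2**31))
            idx += 1
            trials, platform = synth.standing_perturbation_trials(
                subject,
                side=side,
                direction=direction,
                n_trials=n_trials,
                seed=sub_seed,
                geometry=geometry,
                snr_db=snr_db,
                noise=noise,
                fs=fs,
            )
            fits[(side, direction)] = standing_fit_from_trials(trials, geometry, platform)
    symmetry = {
        direction: symmetry_ratio(fits[("non_dominant", direction)],
                                  fits[("dominant", direction)])
        for direction in DIRECTIONS
    }
    return {"fits": fits, "symmetry": symmetry}


def run_walking_impedance(
    subject,
    n_trials: int = 80,
    seed: int = 0,
    snr_db: Optional[float] = None,
    noise=None,
    cadence_bpm: float = 100.0,
    fs: float = 2000.0,
) -> dict:
    """Walking protocol: stance-phase perturbations with catch subtraction.

    For each side × direction, ``n_trials`` stance-phase trials (half
    perturbed at ~45% of stance, half catch) are synthesized, screened by
    the foot-placement windows and the 3-SD trajectory rule (within each
    group), catch trials are averaged and subtracted from the perturbed
    ones, and the averaged differentials are fit.

    Returns the same structure as :func:`run_standing_impedance` plus a
    ``"rejected"`` count per condition.
    """
    from . import synth

    rng_seeds = np.random.SeedSequence(seed).spawn(len(SIDES) * len(DIRECTIONS))
    fits: dict[tuple[str, str], ImpedanceFit] = {}
    rejected_counts: dict[tuple[str, str], int] = {}
    idx = 0
    for side in SIDES:
        for direction in DIRECTIONS:
            sub_seed = int(rng_seeds[idx].generate_state(1)[0] % (2**31))
            idx += 1
            trials = synth.synth_walking_stance(
                subject,
                side=side,
                direction=direction,
                n_trials=n_trials,
                seed=sub_seed,
                cadence_bpm=cadence_bpm,
                snr_db=snr_db,
                noise=noise,
                fs=fs,
            )
            fit, n_rej = walking_fit_from_trials(trials)
            fits[(side, direction)] = fit
            rejected_counts[(side, direction)] = n_rej
    symmetry = {
        direction: symmetry_ratio(fits[("non_dominant", direction)],
                                  fits[("dominant", direction)])
        for direction in DIRECTIONS
    }
    return {"fits": fits, "symmetry": symmetry, "rejected": rejected_counts}


def _average_trials(trials: Sequence[TrialRecord]) -> TrialRecord:
    """Per-sample average of same-length trials (the catch mean)."""
    if not trials:
        raise InsufficientDataError("no trials to average")
    ref = trials[0]
    def avg(get):
        return ref.ankle_angle.with_values(
            np.mean([get(tr) for tr in trials], axis=0)
        )
    onset = float(np.mean([tr.onset_s for tr in trials if tr.onset_s is not None]))
    return TrialRecord(
        side=ref.side,
        direction=ref.direction,
        perturbed=False,
        ankle_angle=avg(lambda tr: tr.ankle_angle.values),
        platform_angle=avg(lambda tr: tr.platform_angle.values),
        torque=ref.torque.with_values(np.mean([tr.torque.values for tr in trials], axis=0)),
        onset_s=onset,
    )
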