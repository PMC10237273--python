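"""Postural-balance outcomes and the two standing balance protocols.

The single balance outcome is TOTEX, the total excursion of the net CoP:
the planar path length

.. math::

    TOTEX = \\sum_i \\sqrt{(CoP_{AP}[i+1]-CoP_{AP}[i])^2
                           + (CoP_{ML}[i+1]-CoP_{ML}[i])^2}

computed over the full trial.  Larger TOTEX means more postural sway,
i.e. less stable standing.

Two protocols are orchestrated against the synthetic generator:

* **passive** — quiet standing on an admittance-rendered compliant
  surface at each configured stiffness level (same stiffness on both
  plates), the rigid/compliant/highly-compliant design being
  10,000 / 500 / 250 Nm/rad;
* **active** — standing while both platforms oscillate sinusoidally over
  an amplitude × frequency grid (0.5/1.0/1.5° × 0.5/1.0/1.5 Hz) with a
  90° phase offset between the plates.

Human TOTEX magnitudes are subject-dependent; only ordinal effects
(more compliance / bigger oscillation → more sway) are meaningful on
synthetic subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GenerationError, InsufficientDataError
from .forceplate import CoPSeries, PlateGeometry, net_cop, plate_cop
from .impedance import FILTER_CUTOFF_HZ, FILTER_ORDER
from .platform_model import AdmittanceSpec, sinusoid_pair
from .signals import TimeSeries, lowpass_filter

__all__ = [
    "BalanceTrial",
    "BalanceOutcome",
    "totex",
    "analyze_balance_trial",
    "run_passive_balance",
    "run_active_balance",
    "PASSIVE_STIFFNESS_LEVELS",
    "ACTIVE_AMPLITUDES_DEG",
    "ACTIVE_FREQUENCIES_HZ",
]

PASSIVE_STIFFNESS_LEVELS = (10000.0, 500.0, 250.0)
ACTIVE_AMPLITUDES_DEG = (0.5, 1.0, 1.5)
ACTIVE_FREQUENCIES_HZ = (0.5, 1.0, 1.5)


@dataclass
class BalanceTrial:
    """One 60 s standing trial: condition label plus the raw recordings."""

    condition: str
    trial_id: int
    duration_s: float
    left_plate: "object"  # ForcePlateSeries
    right_plate: "object"
    platform_commands: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BalanceOutcome:
    """TOTEX (cm) of the net CoP for one trial."""

    condition: str
    trial_id: int
    totex_cm: float
    flagged: bool = False
    note: str = ""


def totex(cop: CoPSeries) -> float:
    """Total excursion (cm): path length of the planar CoP trajectory.

    Invalid samples are skipped; the path is summed over consecutive
    pairs of valid samples.  Needs at least two valid samples.
    """
    valid = cop.valid
    if int(valid.sum()) < 2:
        raise InsufficientDataError("TOTEX needs at least 2 valid CoP samples")
    both = valid[:-1] & valid[1:]
    d_ap = np.diff(cop.ap.values)[both]
    d_ml = np.diff(cop.ml.values)[both]
    return float(np.sum(np.hypot(d_ap, d_ml)))


def analyze_balance_trial(
    trial: BalanceTrial,
    geometry: PlateGeometry,
    inter_plate_distance_cm: float = 25.0,
    filter_cutoff_hz: float = FILTER_CUTOFF_HZ,
) -> BalanceOutcome:
    """Net-CoP TOTEX of one trial through the full reconstruction chain.

    Plate channels are low-pass filtered (15 Hz zero-phase), per-plate
    CoPs and vertical reactions computed, fused into the net CoP with
    the vertical-reaction weighting, and reduced to TOTEX over the full
    trial window.
    """
    def lp(s: TimeSeries) -> TimeSeries:
        return lowpass_filter(s, filter_cutoff_hz, FILTER_ORDER)

    left = trial.left_plate.map(lp)
    right = trial.right_plate.map(lp)
    cop_l = plate_cop(left, geometry)
    cop_r = plate_cop(right, geometry)
    cop_net = net_cop(
        cop_l, cop_r, left.total_normal, right.total_normal,
        inter_plate_distance_cm=inter_plate_distance_cm,
    )
    return BalanceOutcome(
        condition=trial.condition,
        trial_id=trial.trial_id,
        totex_cm=totex(cop_net),
    )


def _randomized_schedule(labels: Sequence, trials_per: int, rng) -> list:
    schedule = [(lbl, t) for lbl in labels for t in range(trials_per)]
    order = rng.permutation(len(schedule))
    return [schedule[i] for i in order]


def run_passive_balance(
    subject,
    stiffness_levels: Sequence[float] = PASSIVE_STIFFNESS_LEVELS,
    trials_per_level: int = 3,
    seed: int = 0,
    duration_s: float = 60.0,
    geometry: Optional[PlateGeometry] = None,
    noise=None,
    inter_plate_distance_cm: float = 25.0,
    fs: float = 2000.0,
) -> list[BalanceOutcome]:
    """Compliant-surface protocol: TOTEX per trial per stiffness level.

    Both platforms render the same stiffness for each condition; trial
    order is randomized by ``seed``.  A trial whose admittance simulation
    diverges is returned flagged (TOTEX NaN), never silently dropped.
    """
    from . import synth

    if any(k <= 0 for k in stiffness_levels):
        raise ValueError("stiffness levels must be positive")
    geometry = geometry or synth.default_geometry()
    noise = noise if noise is not None else synth.NOISELESS
    rng = np.random.default_rng(seed)
    schedule = _randomized_schedule(list(stiffness_levels), trials_per_level, rng)
    outcomes = []
    for run_idx, (k_sim, trial_idx) in enumerate(schedule):
        label = f"k={k_sim:g}"
        trial_seed = int(rng.integers(0, 2**31))
        try:
            rec = synth.synth_standing(
                subject,
                noise=noise,
                duration_s=duration_s,
                admittance=AdmittanceSpec(k_sim=float(k_sim)),
                geometry=geometry,
                fs=fs,
                seed=trial_seed,
            )
            trial = BalanceTrial(
                condition=label,
                trial_id=trial_idx,
                duration_s=duration_s,
                left_plate=rec.left_plate,
                right_plate=rec.right_plate,
                meta={"run_order": run_idx, "seed": trial_seed},
            )
            outcomes.append(
                analyze_balance_trial(trial, geometry, inter_plate_distance_cm)
            )
        except GenerationError as err:
            outcomes.append(
                BalanceOutcome(label, trial_idx, float("nan"), flagged=True, note=str(err))
            )
    return outcomes


def run_active_balance(
    subject,
    amplitudes_deg: Sequence[float] = ACTIVE_AMPLITUDES_DEG,
    frequencies_hz: Sequence[float] = ACTIVE_FREQUENCIES_HZ,
    trials_per_cell: int = 3,
    seed: int = 0,
    duration_s: float = 60.0,
    geometry: Optional[PlateGeometry] = None,
    noise=None,
    inter_plate_distance_cm: float = 25.0,
    phase_offset_deg: float = 90.0,
    fs: float = 2000.0,
) -> list[BalanceOutcome]:
    """Oscillatory protocol: TOTEX per trial per amplitude × frequency cell.

    Both platforms oscillate at the cell's amplitude and frequency with a
    90° phase offset (so they never move the same way); 3 amplitudes × 3
    frequencies × 3 trials gives the full 27-trial design.  Commands are
    range-of-motion validated before any trial runs.
    """
    from . import synth

    if not amplitudes_deg or not frequencies_hz:
        raise ValueError("amplitude/frequency grid must be nonempty")
    geometry = geometry or synth.default_geometry()
    noise = noise if noise is not None else synth.NOISELESS
    rng = np.random.default_rng(seed)
    cells = [(a, f) for a in amplitudes_deg for f in frequencies_hz]
    schedule = _randomized_schedule(cells, trials_per_cell, rng)
    outcomes = []
    for run_idx, ((amp, freq), trial_idx) in enumerate(schedule):
        label = f"A={amp:g}deg_f={freq:g}Hz"
        trial_seed = int(rng.integers(0, 2**31))
        left_cmd, right_cmd = sinusoid_pair(
            amp, freq, fs, duration_s, phase_offset_deg=phase_offset_deg
        )
        zeros = left_cmd.with_values(np.zeros(len(left_cmd)))
        motion = {
            "left": {"DP": left_cmd, "IE": zeros},
            "right": {"DP": right_cmd, "IE": zeros},
        }
        rec = synth.synth_standing(
            subject,
            noise=noise,
            duration_s=duration_s,
            platform_motion=motion,
            geometry=geometry,
            fs=fs,
            seed=trial_seed,
        )
        trial = BalanceTrial(
            condition=label,
            trial_id=trial_idx,
            duration_s=duration_s,
            left_plate=rec.left_plate,
            right_plate=rec.right_plate,
            platform_commands=motion,
            meta={"run_order": run_idx, "seed": trial_seed},
        )
        outcomes.append(analyze_balance_trial(trial, geometry, inter_plate_distance_cm))
    return outcomes
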