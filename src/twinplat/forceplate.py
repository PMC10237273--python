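"""Force-plate mechanics: ankle torques, per-plate CoP, and net CoP.

Each plate reports eight load-cell channels: normal forces ``Fn1..Fn4`` at
the corners and shear forces ``Fs1..Fs4`` along the edges.  With the plate
lever arms (``a``, ``b`` anterior/posterior to the DP axis, ``c``
medio-lateral to the IE axis, ``d`` the height from the load-cell plane to
the ankle IE axis) the ankle torques are reconstructed per sample as

.. math::

    \\tau_{DP} = (F_{n1}+F_{n4})a - (F_{n2}+F_{n3})b + (F_{s1}+F_{s2})d
                 - \\tau_{Platform,DP}

    \\tau_{IE} = (F_{n1}+F_{n2}-F_{n3}-F_{n4})c + (F_{s3}+F_{s4})d
                 - \\tau_{Platform,IE}

where the platform torques account for the dynamics (dominantly inertia)
of the moving plate itself.

The per-plate CoP is the normal-force moment divided by the total normal
load, reported in cm in each plate's local frame centred on its rotation
axes.  The net CoP fuses the two plates with the printed vertical-reaction
weighting

.. math::

    CoP_{net} = \\frac{VR_{right}}{VR_{right}+VR_{left}} CoP_{right}
              + \\frac{VR_{left}}{VR_{right}+VR_{left}} CoP_{left}

after mapping both plates into a shared frame separated by the configured
inter-plate distance.  Samples on an unloaded plate (total normal force
below a floor, default 20 N) are flagged invalid rather than dividing by
a vanishing load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GridMismatchError, InvalidParameterError
from .signals import TimeSeries

__all__ = [
    "PlateGeometry",
    "ForcePlateSeries",
    "CoPSeries",
    "ankle_torques",
    "plate_cop",
    "net_cop",
]

#: default minimum total normal load (N) for a valid CoP sample
DEFAULT_MIN_LOAD_N = 20.0


@dataclass(frozen=True)
class PlateGeometry:
    """Lever-arm dimensions (m) used in torque reconstruction.

    ``a``: front corners to the DP axis; ``b``: rear corners to the DP
    axis; ``c``: corners to the IE axis; ``d``: height from the load-cell
    plane to the ankle IE axis.  ``d`` may be zero (shear terms vanish).
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise InvalidParameterError("plate lever arms a, b, c must be positive")
        if self.d < 0:
            raise InvalidParameterError("height d must be non-negative")


_CHANNELS = ("fn1", "fn2", "fn3", "fn4", "fs1", "fs2", "fs3", "fs4")


@dataclass(frozen=True)
class ForcePlateSeries:
    """The 8 synchronized load-cell channels of one plate (N)."""

    fn1: TimeSeries
    fn2: TimeSeries
    fn3: TimeSeries
    fn4: TimeSeries
    fs1: TimeSeries
    fs2: TimeSeries
    fs3: TimeSeries
    fs4: TimeSeries

    def __post_init__(self):
        for name in _CHANNELS[1:]:
            self.fn1.require_same_grid(getattr(self, name), what=f"plate channel {name}")

    @classmethod
    def from_arrays(cls, fs: float, t0: float = 0.0, **arrays) -> "ForcePlateSeries":
        missing = set(_CHANNELS) - set(arrays)
        if missing:
            raise InvalidParameterError(f"missing plate channels: {sorted(missing)}")
        return cls(**{
            k: TimeSeries(np.asarray(arrays[k], dtype=float), fs=fs, t0=t0, units="N")
            for k in _CHANNELS
        })

    @property
    def channels(self) -> dict[str, TimeSeries]:
        return {k: getattr(self, k) for k in _CHANNELS}

    @property
    def total_normal(self) -> TimeSeries:
        """Total normal (vertical reaction) force, N."""
        tot = self.fn1.values + self.fn2.values + self.fn3.values + self.fn4.values
        return self.fn1.with_values(tot, units="N")

    def map(self, fn) -> "ForcePlateSeries":
        """Apply ``fn`` (TimeSeries -> TimeSeries) to every channel."""
        return ForcePlateSeries(**{k: fn(getattr(self, k)) for k in _CHANNELS})


@dataclass(frozen=True)
class CoPSeries:
    """Planar CoP displacement in cm; invalid samples are NaN + mask False."""

    ap: TimeSeries
    ml: TimeSeries
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.ap.require_same_grid(self.ml, what="CoP ml vs ap")
        v = self.valid
        if v is None:
            v = np.ones(len(self.ap), dtype=bool)
        v = np.asarray(v, dtype=bool)
        if v.shape != (len(self.ap),):
            raise InvalidParameterError("valid mask length must match the CoP grid")
        object.__setattr__(self, "valid", v)

    @property
    def fs(self) -> float:
        return self.ap.fs

    def __len__(self) -> int:
        return len(self.ap)


def _platform_torque_or_zero(ref: TimeSeries, tau: Optional[TimeSeries], name: str):
    if tau is None:
        return np.zeros(len(ref))
    ref.require_same_grid(tau, what=name)
    return tau.values


def ankle_torques(
    fp: ForcePlateSeries,
    geom: PlateGeometry,
    platform_torque_dp: Optional[TimeSeries] = None,
    platform_torque_ie: Optional[TimeSeries] = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Reconstruct ankle DP and IE torques (Nm) from the 8 plate channels.

    ``platform_torque_dp/ie`` are the torques induced by the moving
    platform itself (from platform system identification); ``None`` means
    a static platform (zero compensation).
    """
    tau_p_dp = _platform_torque_or_zero(fp.fn1, platform_torque_dp, "platform DP torque")
    tau_p_ie = _platform_torque_or_zero(fp.fn1, platform_torque_ie, "platform IE torque")
    tau_dp = (
        (fp.fn1.values + fp.fn4.values) * geom.a
        - (fp.fn2.values + fp.fn3.values) * geom.b
        + (fp.fs1.values + fp.fs2.values) * geom.d
        - tau_p_dp
    )
    tau_ie = (
        (fp.fn1.values + fp.fn2.values - fp.fn3.values - fp.fn4.values) * geom.c
        + (fp.fs3.values + fp.fs4.values) * geom.d
        - tau_p_ie
    )
    return (
        fp.fn1.with_values(tau_dp, units="Nm"),
        fp.fn1.with_values(tau_ie, units="Nm"),
    )


def plate_cop(
    fp: ForcePlateSeries,
    geom: PlateGeometry,
    min_load_n: float = DEFAULT_MIN_LOAD_N,
) -> CoPSeries:
    """Per-plate CoP (cm) in the plate's local axis frame.

    Samples with total normal force below ``min_load_n`` (an unloaded
    plate) are marked invalid.
    """
    fn1, fn2, fn3, fn4 = (fp.fn1.values, fp.fn2.values, fp.fn3.values, fp.fn4.values)
    total = fn1 + fn2 + fn3 + fn4
    valid = total >= min_load_n
    with np.errstate(divide="ignore", invalid="ignore"):
        ap_m = ((fn1 + fn4) * geom.a - (fn2 + fn3) * geom.b) / total
        ml_m = (fn1 + fn2 - fn3 - fn4) * geom.c / total
    ap_cm = np.where(valid, ap_m * 100.0, np.nan)
    ml_cm = np.where(valid, ml_m * 100.0, np.nan)
    return CoPSeries(
        ap=fp.fn1.with_values(ap_cm, units="cm"),
        ml=fp.fn1.with_values(ml_cm, units="cm"),
        valid=valid,
    )


def net_cop(
    left: CoPSeries,
    right: CoPSeries,
    vr_left: TimeSeries,
    vr_right: TimeSeries,
    inter_plate_distance_cm: float = 0.0,
) -> CoPSeries:
    """Net CoP: per-plate CoPs fused by vertical-reaction weighting.

    The right CoP is weighted by the right-side vertical reaction fraction
    and the left CoP by the left-side fraction, per axis per sample.  Both
    plates are first mapped into a shared frame: the left IE axis sits at
    ``-D/2`` and the right at ``+D/2`` on the global ML axis, with
    ``D = inter_plate_distance_cm``.  Samples where the total vertical
    reaction is not positive (or either plate CoP is invalid) are flagged
    invalid.
    """
    left.ap.require_same_grid(right.ap, what="left vs right CoP")
    left.ap.require_same_grid(vr_left, what="left vertical reaction")
    left.ap.require_same_grid(vr_right, what="right vertical reaction")
    d2 = inter_plate_distance_cm / 2.0
    total = vr_left.values + vr_right.values
    valid = left.valid & right.valid & (total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_r = vr_right.values / total
    w_l = 1.0 - w_r
    ap = w_r * right.ap.values + w_l * left.ap.values
    ml = w_r * (right.ml.values + d2) + w_l * (left.ml.values - d2)
    ap = np.where(valid, ap, np.nan)
    ml = np.where(valid, ml, np.nan)
    return CoPSeries(
        ap=left.ap.with_values(ap, units="cm"),
        ml=left.ml.with_values(ml, units="cm"),
        valid=valid,
    )
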