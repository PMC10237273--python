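"""Uniformly sampled time series and the signal primitives used everywhere.

The platform records every channel on a uniform 2 kHz grid; all downstream
processing assumes that grid.  This module provides the immutable
:class:`TimeSeries` container, zero-phase Butterworth low-pass filtering,
the five-point midpoint numerical derivative, and rising-edge
synchronization of two independently clocked recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as _sps

from .errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    SyncFailureError,
)

__all__ = [
    "TimeSeries",
    "lowpass_filter",
    "five_point_derivative",
    "align_by_sync_edge",
]

#: tolerance (s) when checking grid uniformity / compatibility
GRID_TOL_S = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """One uniformly sampled real-valued channel.

    Parameters
    ----------
    values : ndarray
        Ordered samples; 1-D, length >= 1.
    fs : float
        Sampling rate in Hz (> 0); sample spacing is exactly ``1/fs``.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Free-form unit label carried as metadata (e.g. ``"deg"``, ``"N"``).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidParameterError("TimeSeries values must be 1-D")
        if v.size < 1:
            raise InsufficientDataError("TimeSeries needs at least one sample")
        if not (self.fs > 0):
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (len(self) - 1) / self.fs

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.fs

    def with_values(self, values, units: str | None = None) -> "TimeSeries":
        """Same grid, new samples (and optionally a new unit label)."""
        return replace(
            self, values=np.asarray(values, dtype=float),
            units=self.units if units is None else units,
        )

    def shifted(self, dt: float) -> "TimeSeries":
        """Time-shift the series by ``dt`` seconds (t0 -> t0 + dt)."""
        return replace(self, t0=self.t0 + dt)

    def same_grid(self, other: "TimeSeries") -> bool:
        return (
            len(self) == len(other)
            and abs(self.fs - other.fs) <= GRID_TOL_S * self.fs * self.fs
            and abs(self.t0 - other.t0) <= GRID_TOL_S
        )

    def require_same_grid(self, other: "TimeSeries", what: str = "series"):
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: grids differ "
                f"(n={len(self)}/{len(other)}, fs={self.fs}/{other.fs}, "
                f"t0={self.t0}/{other.t0})"
            )

    def slice_time(self, t_start: float, t_end: float) -> "TimeSeries":
        """Sub-series covering [t_start, t_end] (inclusive, snapped to grid)."""
        i0 = int(np.ceil((t_start - self.t0) * self.fs - 1e-9))
        i1 = int(np.floor((t_end - self.t0) * self.fs + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self) - 1)
        if i1 < i0:
            raise InsufficientDataError("empty time slice")
        return TimeSeries(self.values[i0 : i1 + 1], self.fs,
                          self.t0 + i0 / self.fs, self.units)


def lowpass_filter(x: TimeSeries, cutoff_hz: float, order: int = 4) -> TimeSeries:
    """Zero-phase Butterworth low-pass filter.

    The filter of the stated order is applied forward and backward
    (``scipy.signal.filtfilt``), so the magnitude response is the squared
    Butterworth magnitude — the effective attenuation order is doubled and
    the phase is identically zero.  Offline analysis only.

    Parameters
    ----------
    x : TimeSeries
    cutoff_hz : float
        -3 dB cutoff of the underlying one-pass design; must be below
        Nyquist.
    order : int
        One-pass filter order (>= 1); the platform's convention is 4.
    """
    if order < 1:
        raise InvalidParameterError(f"order must be >= 1, got {order}")
    if not (0 < cutoff_hz < x.fs / 2):
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={x.fs / 2} Hz)"
        )
    if len(x) < 3 * order:
        raise InsufficientDataError(
            f"need at least {3 * order} samples for order {order}, got {len(x)}"
        )
    b, a = _sps.butter(order, cutoff_hz, btype="low", fs=x.fs)
    padlen = min(3 * max(len(a), len(b)), len(x) - 1)
    y = _sps.filtfilt(b, a, x.values, padlen=padlen)
    return x.with_values(y)


def five_point_derivative(x: TimeSeries) -> TimeSeries:
    """Five-point midpoint numerical derivative.

    Interior samples use the fourth-order midpoint stencil
    ``(f[i-2] - 8 f[i-1] + 8 f[i+1] - f[i+2]) / (12 h)``, which is exact
    for polynomials of degree <= 4.  The two samples at each edge fall back
    to one-sided second-order differences.  Output length equals input
    length; the unit label gains a ``/s``.
    """
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"five-point derivative needs >= 5 samples, got {n}")
    f = x.values
    h = 1.0 / x.fs
    d = np.empty_like(f)
    d[2:-2] = (f[:-4] - 8 * f[1:-3] + 8 * f[3:-1] - f[4:]) / (12 * h)
    # one-sided second-order differences at the boundaries
    d[0] = (-3 * f[0] + 4 * f[1] - f[2]) / (2 * h)
    d[1] = (-3 * f[1] + 4 * f[2] - f[3]) / (2 * h)
    d[-2] = (3 * f[-2] - 4 * f[-3] + f[-4]) / (2 * h)
    d[-1] = (3 * f[-1] - 4 * f[-2] + f[-3]) / (2 * h)
    units = f"{x.units}/s" if x.units else ""
    return x.with_values(d, units=units)


def _single_rising_edge_time(sync: TimeSeries) -> float:
    """Time of the unique low->high transition of a sync channel.

    The detection threshold is half of the channel's peak-to-peak range.
    """
    v = sync.values
    ptp = float(np.max(v) - np.min(v))
    if ptp <= 0:
        raise SyncFailureError("sync channel is constant; no rising edge")
    thr = float(np.min(v)) + ptp / 2.0
    above = v >= thr
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        # already high at the start counts as an edge we cannot time
        raise SyncFailureError("sync channel starts high; rising edge not captured")
    if edges.size != 1:
        raise SyncFailureError(f"expected exactly one rising edge, found {edges.size}")
    return sync.t0 + edges[0] / sync.fs


def align_by_sync_edge(
    a: Mapping[str, TimeSeries],
    a_sync: TimeSeries,
    b: Mapping[str, TimeSeries],
    b_sync: TimeSeries,
) -> tuple[dict[str, TimeSeries], dict[str, TimeSeries]]:
    """Align two recording sets on their sync-channel rising edges.

    Both sets are time-shifted so each set's sync rising edge sits at
    ``t = 0``, then trimmed to the common overlap.  The two recordings must
    share a sampling rate (the platform's two controllers do); after the
    shift, sample grids coincide up to the sub-sample part of the edge
    offset, which for digital sync pulses is an integer number of samples.

    Returns the (shifted, trimmed) copies of ``a`` and ``b``.
    """
    for name, s in {**dict(a), "<a_sync>": a_sync}.items():
        if abs(s.fs - b_sync.fs) > GRID_TOL_S * s.fs * s.fs:
            raise GridMismatchError(f"{name}: sampling rates differ across recordings")
    ta = _single_rising_edge_time(a_sync)
    tb = _single_rising_edge_time(b_sync)

    a_shifted = {k: s.shifted(-ta) for k, s in a.items()}
    b_shifted = {k: s.shifted(-tb) for k, s in b.items()}
    everything = list(a_shifted.values()) + list(b_shifted.values())
    start = max(s.t0 for s in everything)
    end = min(s.t_end for s in everything)
    if end < start:
        raise SyncFailureError("recordings do not overlap after alignment")
    a_out = {k: s.slice_time(start, end) for k, s in a_shifted.items()}
    b_out = {k: s.slice_time(start, end) for k, s in b_shifted.items()}
    return a_out, b_out
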