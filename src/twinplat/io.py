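"""CSV interchange for time-series recordings.

Format: a header row, first column ``time_s``, remaining columns named
channels.  The sampling grid must be uniform; on read it is validated to
1 ns and the rate is inferred from the median spacing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingInputError
from .signals import TimeSeries

__all__ = ["read_timeseries_csv", "write_timeseries_csv"]


def read_timeseries_csv(path) -> dict[str, TimeSeries]:
    """Read a multi-channel time-series CSV into named :class:`TimeSeries`."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"time-series CSV not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise InvalidParameterError(
            f"{path}: first column must be 'time_s' followed by channel columns"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidParameterError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    if np.any(np.abs(dt - np.median(dt)) > 1e-9):
        raise InvalidParameterError(f"{path}: sampling grid is not uniform to 1e-9 s")
    fs = 1.0 / float(np.median(dt))
    return {
        name: TimeSeries(df[name].to_numpy(dtype=float), fs=fs, t0=float(t[0]))
        for name in df.columns[1:]
    }


def write_timeseries_csv(path, channels: Mapping[str, TimeSeries]) -> None:
    """Write named channels sharing one grid to a time-series CSV."""
    channels = dict(channels)
    if not channels:
        raise InvalidParameterError("no channels to write")
    first = next(iter(channels.values()))
    for name, s in channels.items():
        first.require_same_grid(s, what=name)
    df = pd.DataFrame({"time_s": first.t})
    for name, s in channels.items():
        df[name] = s.values
    df.to_csv(path, index=False, float_format="%.10g")
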