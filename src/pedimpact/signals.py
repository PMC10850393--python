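"""Uniformly sampled crash-signal channels and their conditioning.

Internal unit conventions: time in ms, linear acceleration in g
(1 g = 9.80665 m/s^2), angular velocity in rad/s. A channel is a single
physical signal on a strictly increasing uniform time base; the channel
frequency class (CFC) of any low-pass conditioning applied to it travels
with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

STANDARD_GRAVITY = 9.80665  # m/s^2

#: -3 dB cutoff (Hz) of the zero-phase 4-pole Butterworth for each channel
#: frequency class, per the crash-test channel specification (CFC x 5/3).
CFC_CUTOFF_HZ = {
    "CFC60": 100.0,
    "CFC180": 300.0,
    "CFC600": 1000.0,
    "CFC1000": 1650.0,
}


@dataclass(frozen=True)
class TimeSeriesChannel:
    """One uniformly sampled physical signal.

    Parameters
    ----------
    times : ndarray
        Sample times in ms, strictly increasing and uniform.
    values : ndarray
        Sample values, same length as ``times``.
    units : str
        Physical units label (e.g. ``"g"``, ``"rad/s"``).
    name : str
        Channel label (e.g. ``"ax"``).
    filter_class : str or None
        CFC label of the last low-pass applied, if any.
    """

    times: np.ndarray
    values: np.ndarray
    units: str
    name: str = "channel"
    filter_class: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly sampled")
        if not self.units:
            raise ValueError("units label is required")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        if self.times.size < 2:
            raise ValueError("need at least two samples for a sample interval")
        return float(self.times[1] - self.times[0])

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / self.dt

    def __len__(self) -> int:
        return int(self.times.size)


def same_time_base(*channels: TimeSeriesChannel) -> bool:
    first = channels[0]
    return all(
        len(c) == len(first) and np.array_equal(c.times, first.times)
        for c in channels[1:]
    )


def resultant(x: TimeSeriesChannel, y: TimeSeriesChannel, z: TimeSeriesChannel) -> TimeSeriesChannel:
    """Per-sample Euclidean norm of three matched channels."""
    if not same_time_base(x, y, z):
        raise ValueError("resultant requires identical time bases")
    if not (x.units == y.units == z.units):
        raise ValueError(f"resultant requires identical units, got {x.units}/{y.units}/{z.units}")
    vals = np.sqrt(x.values**2 + y.values**2 + z.values**2)
    return TimeSeriesChannel(x.times, vals, x.units, name="resultant",
                             filter_class=x.filter_class)


def cfc_filter(channel: TimeSeriesChannel, cfc_class: str = "CFC1000") -> TimeSeriesChannel:
    """Zero-phase 4-pole low-pass per channel frequency class.

    Implemented as a 2-pole Butterworth applied forward and backward
    (``filtfilt``), giving a 4-pole zero-phase response with unit DC gain.
    """
    if cfc_class not in CFC_CUTOFF_HZ:
        raise ValueError(f"unknown channel class {cfc_class!r}; expected one of {sorted(CFC_CUTOFF_HZ)}")
    cutoff = CFC_CUTOFF_HZ[cfc_class]
    fs = channel.sample_rate_hz
    if fs <= 2.0 * cutoff:
        raise ValueError(
            f"sample rate {fs:.0f} Hz too low for {cfc_class} (cutoff {cutoff:.0f} Hz)"
        )
    b, a = _sig.butter(2, cutoff / (fs / 2.0))
    filtered = _sig.filtfilt(b, a, channel.values)
    return replace(channel, values=filtered, filter_class=cfc_class)


# ---------------------------------------------------------------------------
# columnar CSV I/O with a sidecar metadata block (# key: value comment lines)

def write_channels_csv(path: str | Path, channels: list[TimeSeriesChannel]) -> None:
    if not channels or not same_time_base(*channels):
        raise ValueError("need >=1 channels on one time base")
    path = Path(path)
    lines = []
    for c in channels:
        lines.append(f"# channel: {c.name}; units: {c.units}; "
                     f"filter_class: {c.filter_class or 'none'}")
    lines.append(f"# sample_interval_ms: {channels[0].dt if len(channels[0]) > 1 else 'nan'}")
    df = pd.DataFrame({"time_ms": channels[0].times})
    for c in channels:
        df[c.name] = c.values
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_channels_csv(path: str | Path) -> list[TimeSeriesChannel]:
    path = Path(path)
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("# ").strip()
            if body.startswith("channel:"):
                parts = dict(p.split(":", 1) for p in body.split(";"))
                parts = {k.strip(): v.strip() for k, v in parts.items()}
                meta[parts["channel"]] = parts
    df = pd.read_csv(path, comment="#")
    times = df["time_ms"].to_numpy(float)
    out = []
    for col in df.columns:
        if col == "time_ms":
            continue
        m = meta.get(col, {})
        fc = m.get("filter_class")
        out.append(TimeSeriesChannel(
            times, df[col].to_numpy(float),
            units=m.get("units", "unknown"), name=col,
            filter_class=None if fc in (None, "none") else fc,
        ))
    return out
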