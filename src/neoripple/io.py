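"""Shared containers and file dialects.

All interfaces use seconds and microvolts. Signals are stored on disk as
flat little-endian float32, channel-major, with a JSON sidecar holding the
sampling rate, channel count, channel depths and units. Event tables and
spike trains are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "kind",
    "start_s",
    "stop_s",
    "peak_s",
    "peak_amp",
    "halfwidth_s",
    "n_cycles",
    "peak_freq_hz",
]

EVENT_KINDS = {"active", "spw", "ripple", "spwr", "solo_ripple", "ihfo", "movement"}


@dataclass
class TimeSeries:
    """Multichannel extracellular signal.

    data has shape (n_samples, n_channels); fs in Hz; depths_um one entry
    per channel (positive = deeper); units default to microvolts.
    """

    data: np.ndarray
    fs: float
    depths_um: list[float] | None = None
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[0] == 1 and self.data.shape[1] > 1 and self.data.ndim == 2:
            # accept 1-D input as a single channel
            self.data = self.data.T
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        if self.depths_um is not None and len(self.depths_um) != self.n_channels:
            raise ValueError("depths_um length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, idx: int) -> np.ndarray:
        return self.data[:, idx]


@dataclass
class SpikeTrainSet:
    """Sorted spike times (seconds) per unit, plus the recording duration."""

    trains: dict[int, np.ndarray]
    duration_s: float

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for uid, t in self.trains.items():
            t = np.asarray(t, dtype=np.float64)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValueError(f"unit {uid}: spike times not sorted")
            if t.size and (t[0] < 0 or t[-1] > self.duration_s + 1e-9):
                raise ValueError(f"unit {uid}: spike times outside [0, duration]")
            clean[int(uid)] = t
        self.trains = clean

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def all_spikes(self) -> np.ndarray:
        """Pooled population spike times, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.trains.values())))


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="float64") for c in EVENT_COLUMNS}).astype(
        {"kind": "object"}
    )


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Build a validated event table from row dicts (missing fields -> NaN)."""
    if not rows:
        return empty_events()
    df = pd.DataFrame(rows)
    for c in EVENT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[EVENT_COLUMNS].sort_values("start_s", kind="stable").reset_index(drop=True)
    validate_events(df)
    return df


def validate_events(df: pd.DataFrame) -> None:
    if df.empty:
        return
    bad_kind = set(df["kind"].unique()) - EVENT_KINDS
    if bad_kind:
        raise ValueError(f"unknown event kinds: {sorted(bad_kind)}")
    start = df["start_s"].to_numpy(dtype=float)
    stop = df["stop_s"].to_numpy(dtype=float)
    if np.any(stop <= start):
        raise ValueError(f"row {int(np.argmax(stop <= start))}: stop_s <= start_s")
    peaks = df["peak_s"].to_numpy(dtype=float)
    ok = np.isnan(peaks) | ((start <= peaks) & (peaks <= stop))
    if not np.all(ok):
        raise ValueError(f"row {int(np.argmin(ok))}: peak_s outside [start, stop]")


# ---------------------------------------------------------------------------
# signal dialect: flat float32 LE channel-major + JSON sidecar


def write_signal(ts: TimeSeries, path: str | Path) -> None:
    path = Path(path)
    if np.any(~np.isfinite(ts.data)):
        raise ValueError("signal contains non-finite samples")
    # channel-major: all of channel 0, then channel 1, ...
    ts.data.T.astype("<f4").tofile(path)
    sidecar = {
        "fs": ts.fs,
        "n_channels": ts.n_channels,
        "depths_um": ts.depths_um,
        "units": ts.units,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_signal(path: str | Path) -> TimeSeries:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "n_channels"):
        if key not in meta:
            raise ValueError(f"sidecar missing required key '{key}'")
    raw = np.fromfile(path, dtype="<f4")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch != 0:
        raise ValueError(
            f"binary length {raw.size} not divisible by n_channels {n_ch}"
        )
    data = raw.reshape(n_ch, -1).T.astype(np.float64)
    if np.any(~np.isfinite(data)):
        raise ValueError("signal contains non-finite samples")
    return TimeSeries(
        data=data,
        fs=float(meta["fs"]),
        depths_um=meta.get("depths_um"),
        units=meta.get("units", "uV"),
    )


# ---------------------------------------------------------------------------
# CSV dialects


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    validate_events(df)
    df.to_csv(path, index=False)


def read_events(path: str | Path, validate: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event CSV missing columns: {missing}")
    df = df[EVENT_COLUMNS]
    if validate:
        bad = df.index[df["stop_s"] <= df["start_s"]].tolist()
        if bad:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"invalid rows (stop_s <= start_s) at lines {[i + 2 for i in bad]}"
            )
        validate_events(df)
    return df


def write_spikes(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (uid, t)
        for uid, train in sorted(spikes.trains.items())
        for t in train
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_s"]).to_csv(path, index=False)


def read_spikes(path: str | Path, duration_s: float | None = None,
                validate: bool = True) -> SpikeTrainSet:
    df = pd.read_csv(path)
    for c in ("unit_id", "spike_s"):
        if c not in df.columns:
            raise ValueError(f"spike CSV missing column '{c}'")
    trains: dict[int, np.ndarray] = {}
    for uid, grp in df.groupby("unit_id"):
        t = grp["spike_s"].to_numpy(dtype=np.float64)
        if validate and t.size and np.any(np.diff(t) < 0):
            first_bad = int(np.argmax(np.diff(t) < 0))
            line = grp.index[first_bad + 1] + 2
            raise ValueError(f"unit {uid}: unsorted spike time at line {line}")
        trains[int(uid)] = np.sort(t) if not validate else t
    if duration_s is None:
        duration_s = max((t[-1] for t in trains.values() if t.size), default=0.0)
    return SpikeTrainSet(trains=trains, duration_s=float(duration_s))
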