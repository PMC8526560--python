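"""Reading and writing multi-channel physiological recordings and event tables.

The on-disk formats are deliberately plain: comma-separated text with a
mandatory header row, "." decimal and UTF-8 encoding for bit-exact
reproducibility, plus EDF for instrument exports.  A recording is a set of
equally long, uniformly sampled channels (CBFV in cm/s, BP and EtCO2 in
mmHg) with a sampling frequency; an event table carries the labelled
protocol intervals (stimulation cycles, vasoreactivity stages) as half-open
``[start_s, end_s)`` intervals in seconds from recording start.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Event",
    "EventList",
    "EVENT_VOCABULARY",
    "read_recording",
    "write_recording",
    "write_edf",
    "read_events",
    "write_events",
    "read_results",
    "write_results",
]

EVENT_VOCABULARY = frozenset(
    {"stim_on", "rest", "vr_baseline", "vr_hypercapnia", "vr_recovery",
     "vr_hyperventilation"}
)

#: Canonical column order for result tables; extra keys are appended sorted.
RESULT_COLUMNS = (
    "subject", "overshoot_pct", "K", "Tv", "omega", "xi", "ssr", "chi2",
    "converged", "n_cycles_used", "n_cycles_dropped", "mca_overshoot_pct",
    "vrco2_slope", "vrco2_r2", "mfv_sp", "bp_sp", "error_stage", "error",
)


@dataclass
class Recording:
    """Uniformly sampled multi-channel recording.

    channels maps channel name to a 1-D float array; all channels have the
    same length.  Sample ``j`` of every channel corresponds to time
    ``start_time + j/fs`` seconds.
    """

    channels: dict[str, np.ndarray]
    fs: float
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not self.channels:
            raise ValueError("recording has no channels")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        for k, v in self.channels.items():
            if np.isnan(v).any():
                row = int(np.flatnonzero(np.isnan(v))[0])
                raise ValueError(f"channel {k!r} contains NaN at sample {row}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}")
        return self.channels[name]


@dataclass(frozen=True)
class Event:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in EVENT_VOCABULARY:
            raise ValueError(
                f"unknown event label {self.label!r}; "
                f"allowed: {sorted(EVENT_VOCABULARY)}")
        if not self.start_s < self.end_s:
            raise ValueError(
                f"event {self.label!r}: start_s ({self.start_s}) must be < "
                f"end_s ({self.end_s})")


class EventList:
    """Ordered, validated list of protocol events (half-open intervals)."""

    def __init__(self, events: Iterable[Event] = ()) -> None:
        evs = sorted(events, key=lambda e: (e.start_s, e.end_s))
        stim = [e for e in evs if e.label == "stim_on"]
        for a, b in zip(stim, stim[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping stim_on intervals: [{a.start_s}, {a.end_s}) "
                    f"and [{b.start_s}, {b.end_s})")
        self.events: list[Event] = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventList) and self.events == other.events

    def of_label(self, label: str) -> list[Event]:
        return [e for e in self.events if e.label == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.label, e.start_s, e.end_s) for e in self.events],
            columns=["label", "start_s", "end_s"])


def _infer_fs(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError("time_s column is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise ValueError("time_s column is not uniformly sampled")
    return 1.0 / med


def _apply_gap_policy(name: str, x: np.ndarray, fs: float, policy: str,
                      max_gap_s: float) -> np.ndarray:
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if policy == "reject":
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"channel {name!r} has a missing value at row {row}")
    if policy != "interpolate":
        raise ValueError(f"unknown gap policy {policy!r}")
    # linear interpolation over gaps no longer than max_gap_s
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if len(run) / fs > max_gap_s:
            raise ValueError(
                f"channel {name!r}: gap of {len(run) / fs:.3f} s at row "
                f"{run[0]} exceeds max interpolatable gap {max_gap_s} s")
    good = ~bad
    x = x.copy()
    x[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])
    return x


def read_recording(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    fs: float | None = None,
    gap_policy: str = "reject",
    max_gap_s: float = 0.5,
) -> Recording:
    """Read a recording from delimited text (CSV) or EDF.

    CSV files need a header row; a ``time_s`` column, if present, is used
    to infer the sampling frequency (otherwise ``fs`` must be given).
    ``channel_map`` renames file channels to canonical names (e.g.
    ``{"ch1": "PCA"}``); unmapped channels keep their file names.  Missing
    values are rejected by default, or linearly interpolated when
    ``gap_policy="interpolate"`` and the gap is at most ``max_gap_s``.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        rec = _read_csv_recording(path, fs)
    if channel_map:
        missing = [k for k in channel_map if k not in rec.channels]
        if missing:
            raise ValueError(
                f"required channel(s) {missing} not in file "
                f"(has {sorted(rec.channels)})")
        rec.channels = {channel_map.get(k, k): v for k, v in rec.channels.items()}
    for name in list(rec.channels):
        rec.channels[name] = _apply_gap_policy(
            name, rec.channels[name], rec.fs, gap_policy, max_gap_s)
    return rec


def _read_csv_recording(path: Path, fs: float | None) -> Recording:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no samples")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r} at row {row}")
            df[col] = coerced
    if "time_s" in df.columns:
        inferred = _infer_fs(df["time_s"].to_numpy(dtype=float))
        if fs is not None and abs(inferred - fs) > 0.01 * fs:
            raise ValueError(
                f"stated fs {fs} Hz inconsistent with time_s column "
                f"({inferred:.6g} Hz)")
        fs = inferred
        df = df.drop(columns=["time_s"])
    if fs is None:
        raise ValueError(f"{path}: no time_s column and no sampling frequency given")
    channels = {str(c): df[c].to_numpy(dtype=float) for c in df.columns}
    r = Recording.__new__(Recording)  # defer NaN validation to gap policy
    r.channels, r.fs, r.start_time, r.meta = channels, float(fs), 0.0, {}
    lengths = {k: len(v) for k, v in channels.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"channel lengths differ: {lengths}")
    return r


def write_recording(rec: Recording, path: str | Path, float_fmt: str = "%.12g") -> None:
    """Write a recording as CSV with a ``time_s`` column (round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": rec.time(), **rec.channels})
    df.to_csv(path, index=False, float_format=float_fmt)


# --- EDF ---------------------------------------------------------------

def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    channels = {str(nm): data[i] for i, nm in enumerate(raw.ch_names)}
    r = Recording.__new__(Recording)
    r.channels, r.fs, r.start_time, r.meta = channels, float(raw.info["sfreq"]), 0.0, {}
    return r


def write_edf(rec: Recording, path: str | Path,
              phys_dims: Mapping[str, str] | None = None) -> None:
    """Write a recording as a minimal EDF file (16-bit, 1 s data records).

    Samples are quantized to the 16-bit digital range scaled per channel to
    its physical min/max, so the round trip is exact only to about
    ``(max - min) / 2^16`` per channel.  The trailing partial data record
    is padded by repeating the last sample; the reader trims nothing, so
    the stored length is rounded up to a whole number of seconds.
    """
    path = Path(path)
    names = list(rec.channels)
    ns = len(names)
    spr = int(round(rec.fs))
    if abs(spr - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling frequency")
    n = rec.n_samples
    nrec = int(math.ceil(n / spr))
    pad = nrec * spr - n
    dims = dict(phys_dims or {})

    def f(s, w: int) -> bytes:
        return str(s)[:w].ljust(w).encode("ascii")

    header = b"".join([
        f("0", 8), f("nvckit", 80), f("nvckit recording", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(256 * (1 + ns), 8), f("", 44),
        f(nrec, 8), f("1", 8), f(ns, 4),
    ])
    mins, maxs = [], []
    for nm in names:
        x = rec.channels[nm]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        mins.append(lo)
        maxs.append(hi)
    header += b"".join(f(nm, 16) for nm in names)
    header += b"".join(f("", 80) for _ in names)
    header += b"".join(f(dims.get(nm, ""), 8) for nm in names)
    header += b"".join(f("%.8g" % m, 8) for m in mins)
    header += b"".join(f("%.8g" % m, 8) for m in maxs)
    header += b"".join(f(-32768, 8) for _ in names)
    header += b"".join(f(32767, 8) for _ in names)
    header += b"".join(f("", 80) for _ in names)
    header += b"".join(f(spr, 8) for _ in names)
    header += b"".join(f("", 32) for _ in names)

    digital = []
    for i, nm in enumerate(names):
        x = rec.channels[nm]
        if pad:
            x = np.concatenate([x, np.full(pad, x[-1])])
        d = np.round((x - mins[i]) / (maxs[i] - mins[i]) * 65535.0 - 32768.0)
        digital.append(d.astype("<i2").reshape(nrec, spr))
    with open(path, "wb") as fh:
        fh.write(header)
        for r_ in range(nrec):
            for i in range(ns):
                fh.write(digital[i][r_].tobytes())


# --- events ------------------------------------------------------------

def read_events(path: str | Path) -> EventList:
    """Read an event table (columns label, start_s, end_s); sorted on return."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return EventList()
    if df.empty:
        return EventList()
    required = {"label", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: event table must have columns {sorted(required)}, "
            f"got {list(df.columns)}")
    events = [
        Event(str(r.label), float(r.start_s), float(r.end_s))
        for r in df.itertuples(index=False)
    ]
    return EventList(events)


def write_events(events: EventList, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False, float_format="%.12g")


# --- results -----------------------------------------------------------

def write_results(results: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                  float_fmt: str = "%.12g") -> None:
    """Write result records as CSV, one row per subject, fixed column order.

    Columns follow :data:`RESULT_COLUMNS`; any additional keys are appended
    in sorted order so repeated runs are byte-identical.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(list(results))
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=list(RESULT_COLUMNS))
    known = [c for c in RESULT_COLUMNS if c in df.columns]
    extra = sorted(c for c in df.columns if c not in RESULT_COLUMNS)
    df = df[known + extra]
    df.to_csv(path, index=False, float_format=float_fmt)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
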