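"""Beat-level processing of the CBFV envelope.

The TCD instrument reports the velocity envelope at the full acquisition
rate; the quantities of interest for evoked-response analysis are per-beat:
the systolic peak (least artifact-prone), the diastolic minimum, and the
beat-averaged mean velocity.  This module detects systolic peaks, flags
implausible beats, and interpolates per-beat values back onto a uniform
low-rate grid so that a continuous-time model can be fitted downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BeatSeries",
    "UniformSeries",
    "detect_systolic_peaks",
    "beats_to_uniform",
    "flag_artifact_beats",
]


class NoCardiacSignalError(ValueError):
    """Raised when no plausible cardiac peaks can be found in an envelope."""


@dataclass
class UniformSeries:
    """Uniformly sampled scalar series with its own time base."""

    t0: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) / self.fs

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary times; NaN outside the span."""
        return np.interp(t, self.t, self.values, left=np.nan, right=np.nan)


@dataclass
class BeatSeries:
    """Per-beat values extracted from a CBFV envelope.

    ``flags`` marks beats excluded from interpolation (artifact or
    out-of-range inter-beat interval); True means bad.
    """

    beat_times: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray
    mean_v: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.systolic = np.asarray(self.systolic, dtype=float)
        self.diastolic = np.asarray(self.diastolic, dtype=float)
        self.mean_v = np.asarray(self.mean_v, dtype=float)
        n = len(self.beat_times)
        if self.flags is None:
            self.flags = np.zeros(n, dtype=bool)
        self.flags = np.asarray(self.flags, dtype=bool)
        for name in ("systolic", "diastolic", "mean_v", "flags"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != beat_times length")
        if n > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        # The physiologic ordering systolic >= mean >= diastolic can break
        # on artifacted beats (e.g. a probe-slip dropout followed by a
        # normal upstroke inside the same inter-peak interval); such beats
        # are flagged as bad rather than rejected wholesale.
        tol = 1e-9 * np.maximum(1.0, np.abs(self.systolic))
        disordered = (self.systolic + tol < self.mean_v) | (
            self.mean_v + tol < self.diastolic)
        self.flags = self.flags | disordered

    def __len__(self) -> int:
        return len(self.beat_times)

    @property
    def good(self) -> np.ndarray:
        return ~self.flags


def detect_systolic_peaks(
    envelope: np.ndarray,
    fs: float,
    min_hr: float = 40.0,
    max_hr: float = 160.0,
) -> BeatSeries:
    """Detect one systolic peak per cardiac cycle in a CBFV envelope.

    Peaks are local maxima separated by at least ``60/max_hr`` s with
    prominence of at least 10% of the envelope's interquartile range (ties
    broken to the earliest sample by the detector's scan order).  For each
    beat, diastolic is the envelope minimum and mean velocity the envelope
    average over ``[peak_i, peak_{i+1})`` (to the end of the record for the
    last beat).  Beats whose inter-beat interval falls outside the
    ``[min_hr, max_hr]`` bpm band are flagged; if more than 10% of
    intervals are out of band a warning is issued.
    """
    envelope = np.asarray(envelope, dtype=float)
    if not (20 <= min_hr < max_hr <= 220):
        raise ValueError("need 20 <= min_hr < max_hr <= 220 bpm")
    if len(envelope) < 2 * fs:
        raise ValueError("envelope must cover at least 2 s")
    iqr = float(np.subtract(*np.percentile(envelope, [75, 25])))
    if iqr <= 0:
        raise NoCardiacSignalError("no cardiac signal: envelope has no variation")
    distance = max(1, int(round(fs * 60.0 / max_hr)))
    peaks, _ = find_peaks(envelope, distance=distance, prominence=0.1 * iqr)
    if peaks.size == 0:
        raise NoCardiacSignalError("no cardiac signal: no prominent peaks found")

    n = peaks.size
    ends = np.append(peaks[1:], len(envelope))
    systolic = envelope[peaks]
    diastolic = np.empty(n)
    mean_v = np.empty(n)
    for i in range(n):
        seg = envelope[peaks[i]:ends[i]]
        diastolic[i] = seg.min()
        mean_v[i] = seg.mean()

    flags = np.zeros(n, dtype=bool)
    if n > 1:
        ibi = np.diff(peaks) / fs
        out = (ibi < 60.0 / max_hr - 0.5 / fs) | (ibi > 60.0 / min_hr)
        # attribute a bad interval to the beat that terminates it
        flags[1:] |= out
        if out.mean() > 0.10:
            warnings.warn(
                f"{100 * out.mean():.0f}% of inter-beat intervals outside "
                f"[{min_hr:g}, {max_hr:g}] bpm", stacklevel=2)
    return BeatSeries(peaks / fs, systolic, diastolic, mean_v, flags)


def beats_to_uniform(
    beats: BeatSeries,
    field_name: str = "systolic",
    grid_fs: float = 2.0,
) -> UniformSeries:
    """Linearly interpolate a per-beat value onto a uniform grid.

    The grid spans ``[first_beat, last_beat]`` of the unflagged beats at
    ``grid_fs`` Hz (default 2 Hz: the modelled evoked dynamics live well
    below 1 Hz, so this oversamples the response while discarding
    cardiac-frequency content).  Flagged beats are excluded.
    """
    if field_name not in ("systolic", "mean_v", "diastolic"):
        raise ValueError(f"unknown field {field_name!r}")
    if not 1.0 <= grid_fs <= 10.0:
        raise ValueError("grid_fs must be in [1, 10] Hz")
    good = beats.good
    if good.sum() < 2:
        raise ValueError("need at least 2 unflagged beats to interpolate")
    bt = beats.beat_times[good]
    bv = getattr(beats, field_name)[good]
    n = int(np.floor((bt[-1] - bt[0]) * grid_fs)) + 1
    t = bt[0] + np.arange(n) / grid_fs
    return UniformSeries(t0=float(bt[0]), fs=float(grid_fs), values=np.interp(t, bt, bv))


def flag_artifact_beats(
    beats: BeatSeries,
    reference: float,
    lo: float = 0.3,
    hi: float = 3.0,
) -> BeatSeries:
    """Flag beats with implausible systolic values; returns a new series.

    Beats with systolic outside ``[lo * reference, hi * reference]`` are
    flagged (default 0.3-3x the reference, e.g. the recording's median
    systolic: probe-slip artifacts are large, physiologic evoked changes
    are at most ~50%).  Existing flags are preserved.
    """
    if reference <= 0:
        raise ValueError("reference must be > 0")
    bad = (beats.systolic < lo * reference) | (beats.systolic > hi * reference)
    return replace(beats, flags=beats.flags | bad)
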