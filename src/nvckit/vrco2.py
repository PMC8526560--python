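"""CO2 vasoreactivity slope and band-limited variability spectral power.

Vasoreactivity to CO2 (VRCO2) is assessed with successive 2-min stages:
rest, hypercapnia (5% CO2 / 95% O2, raising EtCO2 7-10 mmHg above
baseline), room-air recovery back to normocapnia, and hyperventilation
(EtCO2 7-10 mmHg below baseline).  VRCO2 is the ordinary-least-squares
slope of relative mean CBFV (% of the baseline-stage mean) against the
stage-average EtCO2 over the three analysis stages (baseline, hypercapnia,
hyperventilation; the recovery step is a washout and is excluded),
expressed in % mean CBFV per mmHg EtCO2.

Spectral power quantifies spontaneous flow/pressure variability as the
band-integrated power spectral density of a beat-derived series (mean CBFV
in (cm/s)^2, mean BP in mmHg^2), estimated with an averaged periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.signal import welch

from .beats import detect_systolic_peaks, flag_artifact_beats
from .io import EventList, Recording

__all__ = [
    "StageSummary",
    "VRCO2Result",
    "BandPower",
    "ANALYSIS_STAGES",
    "stage_means",
    "vrco2_slope",
    "band_power",
]

ANALYSIS_STAGES = ("vr_baseline", "vr_hypercapnia", "vr_hyperventilation")


@dataclass(frozen=True)
class StageSummary:
    """Steady-state summary of one vasoreactivity stage."""

    stage: str
    etco2_mean: float   # mmHg
    cbfv_mean: float    # cm/s (beat-averaged mean velocity)
    cbfv_rel: float     # % of the baseline-stage mean (baseline = 100)


@dataclass(frozen=True)
class VRCO2Result:
    slope: float        # % mean CBFV per mmHg EtCO2
    r2: float
    stages: tuple[StageSummary, ...]


@dataclass(frozen=True)
class BandPower:
    band: tuple[float, float]   # Hz
    power: float                # (signal units)^2
    method: str


def stage_means(
    recording: Recording,
    events: EventList,
    cbfv_channel: str = "PCA",
    etco2_channel: str = "EtCO2",
    window_s: float = 60.0,
    min_hr: float = 40.0,
    max_hr: float = 160.0,
) -> list[StageSummary]:
    """Steady-state EtCO2 and mean-CBFV averages for the analysis stages.

    Averages are taken over the last ``window_s`` seconds of each stage
    (default 60 s of a 2-min step, by which time the EtCO2 transition has
    settled); if a stage is shorter than the window, the window shrinks to
    the stage with a warning.  Mean CBFV is the per-beat mean velocity from
    the envelope; relative CBFV is referenced to the baseline stage, so it
    is invariant to rescaling the velocity channel.
    """
    env = recording[cbfv_channel]
    etco2 = recording[etco2_channel]
    beats = detect_systolic_peaks(env, recording.fs, min_hr=min_hr, max_hr=max_hr)
    beats = flag_artifact_beats(beats, float(np.median(beats.systolic)))

    summaries: dict[str, tuple[float, float]] = {}
    for stage in ANALYSIS_STAGES:
        matches = events.of_label(stage)
        if not matches:
            raise ValueError(f"missing vasoreactivity stage {stage!r}")
        ev = matches[0]
        w = window_s
        if ev.end_s - ev.start_s < window_s:
            w = ev.end_s - ev.start_s
            warnings.warn(
                f"stage {stage!r} shorter than averaging window; using "
                f"{w:.1f} s", stacklevel=2)
        t0, t1 = ev.end_s - w, ev.end_s
        i0 = int(np.ceil((t0 - recording.start_time) * recording.fs))
        i1 = int(np.floor((t1 - recording.start_time) * recording.fs))
        etco2_mean = float(etco2[max(i0, 0):i1].mean())
        sel = beats.good & (beats.beat_times >= t0) & (beats.beat_times < t1)
        if not sel.any():
            raise ValueError(f"no usable beats in stage {stage!r}")
        cbfv_mean = float(beats.mean_v[sel].mean())
        summaries[stage] = (etco2_mean, cbfv_mean)

    base_cbfv = summaries["vr_baseline"][1]
    return [
        StageSummary(stage=s, etco2_mean=e, cbfv_mean=c,
                     cbfv_rel=100.0 * c / base_cbfv)
        for s, (e, c) in summaries.items()
    ]


def vrco2_slope(stages: list[StageSummary]) -> VRCO2Result:
    """OLS slope of relative mean CBFV (%) on EtCO2 (mmHg), three stages.

    Exact on collinear input; invariant to the order in which the stages
    are supplied.  Raises on a degenerate abscissa (identical EtCO2
    means across stages).
    """
    if len(stages) != 3:
        raise ValueError(f"need exactly three stages, got {len(stages)}")
    x = np.array([s.etco2_mean for s in stages])
    y = np.array([s.cbfv_rel for s in stages])
    if np.ptp(x) < 1e-9:
        raise ValueError("degenerate abscissa: identical EtCO2 means across stages")
    xc, yc = x - x.mean(), y - y.mean()
    slope = float(np.dot(xc, yc) / np.dot(xc, xc))
    sst = float(np.dot(yc, yc))
    ssr = float(np.sum((yc - slope * xc) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    return VRCO2Result(slope=slope, r2=r2, stages=tuple(stages))


def band_power(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.02, 0.5),
    segment_s: float = 100.0,
) -> BandPower:
    """Band-integrated power spectral density of a (detrended) series.

    Uses an averaged periodogram (Hann-windowed segments of ``segment_s``
    seconds, 50% overlap, mean removed per segment) and integrates the PSD
    over ``[f_lo, f_hi]``.  For a pure sinusoid of amplitude A inside the
    band the power converges to A^2/2; for white noise over the full band
    it converges to the signal variance (Parseval).
    """
    series = np.asarray(series, dtype=float)
    f_lo, f_hi = band
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"invalid band {band}")
    if f_hi > fs / 2 + 1e-12:
        raise ValueError(f"band upper edge {f_hi} Hz above Nyquist {fs / 2} Hz")
    if f_lo > 0 and len(series) < 4.0 / f_lo * fs:
        raise ValueError(
            f"series too short: need >= {4.0 / f_lo:.0f} s for f_lo = {f_lo} Hz")
    nperseg = min(len(series), int(round(segment_s * fs)))
    f, psd = welch(series, fs=fs, nperseg=nperseg, noverlap=nperseg // 2,
                   detrend="constant")
    df = f[1] - f[0]
    mask = (f >= f_lo) & (f <= f_hi)
    power = float(np.sum(psd[mask]) * df)
    return BandPower(band=(float(f_lo), float(f_hi)), power=power,
                     method=f"averaged periodogram, {nperseg / fs:g} s segments, "
                            "50% overlap, Hann window")
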