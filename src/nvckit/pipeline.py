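"""Subject- and batch-level orchestration of the analysis stages.

Composes ingestion -> beat extraction -> stimulus-locked averaging +
second-order fit (PCA, with the MCA specificity control) -> VRCO2 slope ->
variability band power into one result row per subject.  Partial protocols
(NVC-only or VRCO2-only recordings) produce the computable subset with the
remaining fields missing; stage errors become row-level error records so a
batch keeps going.

Group statistics (ANOVA and friends) are deliberately not implemented: the
result table is designed to be handed to external statistics tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .beats import beats_to_uniform, detect_systolic_peaks, flag_artifact_beats
from .io import EventList, Recording
from .nvc import (AveragedResponse, NVCResult, StimulusProtocol,
                  average_cycles, compute_overshoot, segment_cycles)
from .sos import DEFAULT_BOUNDS, fit_step_response
from .vrco2 import band_power, stage_means, vrco2_slope

log = logging.getLogger("nvckit")

__all__ = ["PipelineConfig", "run_subject", "run_batch", "analyze_nvc",
           "analyze_vrco2"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable analysis parameters, loadable from YAML.

    Unknown keys are rejected on load so typos cannot silently fall back
    to defaults.
    """

    channel_map: dict[str, str] = field(default_factory=dict)
    pca_channel: str = "PCA"
    mca_channel: str = "MCA"
    bp_channel: str = "BP"
    etco2_channel: str = "EtCO2"
    protocol: StimulusProtocol = StimulusProtocol()
    min_hr: float = 40.0
    max_hr: float = 160.0
    grid_fs: float = 2.0
    artifact_lo: float = 0.3
    artifact_hi: float = 3.0
    max_flagged_frac: float = 0.2
    normalization: str = "per_cycle"
    fit_multi_start: bool = False
    fit_bounds: tuple = DEFAULT_BOUNDS
    vrco2_window_s: float = 60.0
    band: tuple[float, float] = (0.02, 0.5)
    gap_policy: str = "reject"
    float_fmt: str = "%.12g"

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "protocol" in d and isinstance(d["protocol"], dict):
            pknown = set(StimulusProtocol.__dataclass_fields__)
            punknown = set(d["protocol"]) - pknown
            if punknown:
                raise ValueError(f"unknown protocol key(s): {sorted(punknown)}")
            d["protocol"] = StimulusProtocol(**d["protocol"])
        for key in ("band", "fit_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(tuple(x) if isinstance(x, list) else x for x in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["band"] = list(self.band)
        d["fit_bounds"] = [list(b) for b in self.fit_bounds]
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _nvc_channel(recording: Recording, events: EventList, channel: str,
                 cfg: PipelineConfig) -> tuple[AveragedResponse, int]:
    beats = detect_systolic_peaks(recording[channel], recording.fs,
                                  min_hr=cfg.min_hr, max_hr=cfg.max_hr)
    beats = flag_artifact_beats(beats, float(np.median(beats.systolic)),
                                lo=cfg.artifact_lo, hi=cfg.artifact_hi)
    series = beats_to_uniform(beats, "systolic", grid_fs=cfg.grid_fs)
    seg = segment_cycles(series, events, cfg.protocol, beats=beats,
                         max_flagged_frac=cfg.max_flagged_frac)
    resp = average_cycles(seg.segments, cfg.protocol,
                          normalization=cfg.normalization, territory=channel)
    return resp, seg.n_dropped


def analyze_nvc(recording: Recording, events: EventList,
                cfg: PipelineConfig = PipelineConfig()) -> NVCResult:
    """Full NVC analysis of one recording: PCA response + fit, MCA control."""
    resp, n_dropped = _nvc_channel(recording, events, cfg.pca_channel, cfg)
    fit = fit_step_response(resp, multi_start=cfg.fit_multi_start,
                            bounds=cfg.fit_bounds)
    mca = None
    if cfg.mca_channel in recording.channels:
        mca_resp, _ = _nvc_channel(recording, events, cfg.mca_channel, cfg)
        mca = compute_overshoot(mca_resp, cfg.protocol.stim_s)
    return NVCResult(
        overshoot_pct=compute_overshoot(resp, cfg.protocol.stim_s), fit=fit,
        mca_overshoot_pct=mca, n_cycles_used=resp.n_cycles_used,
        n_cycles_dropped=n_dropped, response=resp)


def analyze_vrco2(recording: Recording, events: EventList,
                  cfg: PipelineConfig = PipelineConfig()):
    stages = stage_means(recording, events, cbfv_channel=cfg.pca_channel,
                         etco2_channel=cfg.etco2_channel,
                         window_s=cfg.vrco2_window_s,
                         min_hr=cfg.min_hr, max_hr=cfg.max_hr)
    return vrco2_slope(stages)


def _band_powers(recording: Recording, cfg: PipelineConfig) -> dict[str, float]:
    """Variability band power of beat-interpolated mean CBFV and mean BP."""
    out = {"mfv_sp": math.nan, "bp_sp": math.nan}
    try:
        beats = detect_systolic_peaks(recording[cfg.pca_channel], recording.fs,
                                      min_hr=cfg.min_hr, max_hr=cfg.max_hr)
        mfv = beats_to_uniform(beats, "mean_v", grid_fs=cfg.grid_fs)
        out["mfv_sp"] = band_power(mfv.values, mfv.fs, cfg.band).power
        if cfg.bp_channel in recording.channels:
            # per-beat mean BP on the CBFV beat grid, resampled uniformly
            bp = recording[cfg.bp_channel]
            edges = np.round((beats.beat_times - recording.start_time)
                             * recording.fs).astype(int)
            ends = np.append(edges[1:], len(bp))
            means = np.array([bp[a:b].mean() for a, b in zip(edges, ends)])
            grid = mfv.t
            series = np.interp(grid, beats.beat_times, means)
            out["bp_sp"] = band_power(series, mfv.fs, cfg.band).power
    except ValueError:
        pass
    return out


_MISSING = float("nan")


def run_subject(recording_path: str | Path, events_path: str | Path,
                cfg: PipelineConfig = PipelineConfig(),
                subject: str | None = None) -> dict[str, Any]:
    """Analyze one subject; returns a flat result row.

    Stage failures populate ``error_stage``/``error`` instead of raising,
    so batch processing continues past a bad recording.
    """
    subject = subject or Path(recording_path).stem
    row: dict[str, Any] = {"subject": subject}
    for key in ("overshoot_pct", "K", "Tv", "omega", "xi", "ssr", "chi2",
                "mca_overshoot_pct", "vrco2_slope", "vrco2_r2", "mfv_sp",
                "bp_sp"):
        row[key] = _MISSING
    row.update(converged=False, n_cycles_used=0, n_cycles_dropped=0,
               error_stage="", error="")
    try:
        recording = nio.read_recording(recording_path,
                                       channel_map=cfg.channel_map or None,
                                       gap_policy=cfg.gap_policy)
        events = nio.read_events(events_path)
    except Exception as exc:  # noqa: BLE001 - reported as an error row
        row.update(error_stage="signal_io", error=str(exc))
        return row

    if events.of_label("stim_on"):
        try:
            res = analyze_nvc(recording, events, cfg)
            row.update(
                overshoot_pct=res.overshoot_pct, K=res.fit.params.K,
                Tv=res.fit.params.Tv, omega=res.fit.params.omega,
                xi=res.fit.params.xi, ssr=res.fit.ssr, chi2=res.fit.chi2,
                converged=res.fit.converged, n_cycles_used=res.n_cycles_used,
                n_cycles_dropped=res.n_cycles_dropped)
            if res.mca_overshoot_pct is not None:
                row["mca_overshoot_pct"] = res.mca_overshoot_pct
        except Exception as exc:  # noqa: BLE001
            row.update(error_stage="nvc_response", error=str(exc))
            return row

    if events.of_label("vr_baseline"):
        try:
            vr = analyze_vrco2(recording, events, cfg)
            row.update(vrco2_slope=vr.slope, vrco2_r2=vr.r2)
        except Exception as exc:  # noqa: BLE001
            row.update(error_stage="vrco2_spectral", error=str(exc))
            return row

    try:
        row.update(_band_powers(recording, cfg))
    except Exception as exc:  # noqa: BLE001
        row.update(error_stage="vrco2_spectral", error=str(exc))
    return row


def run_batch(manifest: str | Path | pd.DataFrame,
              cfg: PipelineConfig = PipelineConfig(),
              out: str | Path | None = None) -> pd.DataFrame:
    """Run every subject in a manifest (columns subject, recording, events).

    Rows come back in manifest order; per-subject failures are error rows,
    and ok/failed counts are logged.  When ``out`` is given the table is
    written with fixed float formatting, so re-running with identical
    inputs yields a byte-identical file.
    """
    if isinstance(manifest, (str, Path)):
        mdf = pd.read_csv(manifest)
    else:
        mdf = manifest
    if mdf.empty:
        log.warning("empty manifest")
        df = pd.DataFrame(columns=list(nio.RESULT_COLUMNS))
    else:
        rows = []
        for r in mdf.itertuples(index=False):
            subject = getattr(r, "subject", None)
            rows.append(run_subject(r.recording, r.events, cfg, subject=subject))
        df = pd.DataFrame(rows)
        n_fail = int((df["error_stage"] != "").sum())
        log.info("batch: %d ok, %d failed", len(df) - n_fail, n_fail)
    if out is not None:
        nio.write_results(df, out, float_fmt=cfg.float_fmt)
    return df
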