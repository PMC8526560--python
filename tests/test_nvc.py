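"""Cycle segmentation, baseline-referenced averaging, and the overshoot."""

import numpy as np
import pytest

from nvckit.beats import BeatSeries, UniformSeries
from nvckit.io import Event, EventList
from nvckit.nvc import (AveragedResponse, CycleSegment, StimulusProtocol,
                        average_cycles, compute_overshoot, segment_cycles)
from nvckit.pipeline import analyze_nvc
from nvckit.sos import SecondOrderParams, step_response

PROTO = StimulusProtocol()


def _series_with_cycles(n_cycles=10, gfs=2.0, response=None, baseline=40.0):
    """Uniform systolic series for a full paradigm with a known response."""
    proto = StimulusProtocol(n_cycles=n_cycles)
    dur = n_cycles * proto.cycle_s + proto.rest_s
    t = np.arange(0, dur, 1 / gfs)
    v = np.full_like(t, baseline)
    if response is not None:
        for k in range(n_cycles):
            on = proto.rest_s + k * proto.cycle_s
            m = (t >= on) & (t < on + proto.stim_s)
            v[m] = baseline * (1 + response(t[m] - on) / 100.0)
    events = EventList([Event("stim_on", proto.rest_s + k * proto.cycle_s,
                              proto.rest_s + k * proto.cycle_s + proto.stim_s)
                        for k in range(n_cycles)])
    return UniformSeries(t0=0.0, fs=gfs, values=v), events, proto


class TestSegmentCycles:
    def test_clean_paradigm_yields_all_cycles(self):
        series, events, proto = _series_with_cycles()
        seg = segment_cycles(series, events, proto)
        assert len(seg.segments) == 10
        assert seg.n_dropped == 0
        for s in seg.segments:
            assert s.t[0] == pytest.approx(-proto.baseline_s)
            assert s.t[-1] == pytest.approx(proto.stim_s)

    def test_insufficient_prestim_data_drops_cycle(self):
        series, _, proto = _series_with_cycles()
        events = EventList([Event("stim_on", 3.0, 43.0),
                            Event("stim_on", 80.0, 120.0)])
        seg = segment_cycles(series, events, proto)
        assert len(seg.segments) == 1
        assert seg.n_dropped == 1

    def test_cycles_with_many_flagged_beats_dropped(self):
        series, events, proto = _series_with_cycles()
        bt = np.arange(0.5, 620, 1.0)
        flags = np.zeros(bt.size, dtype=bool)
        # corrupt cycles 3 and 7: flag half the beats in their spans
        for k in (3, 7):
            on = proto.rest_s + k * proto.cycle_s
            m = (bt >= on) & (bt < on + proto.stim_s)
            idx = np.flatnonzero(m)[::2]
            flags[idx] = True
        beats = BeatSeries(bt, np.full_like(bt, 40.0), np.full_like(bt, 20.0),
                           np.full_like(bt, 30.0), flags=flags)
        seg = segment_cycles(series, events, proto, beats=beats)
        assert len(seg.segments) == 8
        assert seg.n_dropped == 2

    def test_no_usable_cycles_is_an_error(self):
        series, _, proto = _series_with_cycles(n_cycles=1)
        events = EventList([Event("stim_on", 1.0, 41.0)])
        with pytest.raises(ValueError, match="zero retained"):
            segment_cycles(UniformSeries(0.0, 2.0, series.values[:20]),
                           events, proto)


class TestAverageCycles:
    def test_identical_segments_average_to_themselves(self):
        resp = lambda tt: 15 * (1 - np.exp(-tt / 5))
        series, events, proto = _series_with_cycles(response=resp)
        seg = segment_cycles(series, events, proto)
        avg = average_cycles(seg.segments, proto)
        one = seg.segments[0]
        b = one.v_abs[(one.t >= -5) & (one.t < 0)].mean()
        np.testing.assert_allclose(avg.v_rel, 100 * (one.v_abs / b - 1),
                                   atol=1e-9)
        assert avg.n_cycles_used == 10

    def test_constant_segments_give_zero_relative_change(self):
        series, events, proto = _series_with_cycles()
        seg = segment_cycles(series, events, proto)
        avg = average_cycles(seg.segments, proto)
        np.testing.assert_allclose(avg.v_rel, 0.0, atol=1e-9)
        assert avg.baseline_abs == pytest.approx(40.0)

    def test_normalization_orders_agree_for_equal_baselines(self, rng):
        series, events, proto = _series_with_cycles(
            response=lambda tt: 12 * (1 - np.exp(-tt / 6)))
        seg = segment_cycles(series, events, proto)
        a = average_cycles(seg.segments, proto, normalization="per_cycle")
        b = average_cycles(seg.segments, proto, normalization="grand_mean")
        np.testing.assert_allclose(a.v_rel, b.v_rel, atol=1e-9)

    def test_prestim_mean_is_zero_by_construction(self, rng):
        series, events, proto = _series_with_cycles()
        seg = segment_cycles(series, events, proto)
        for s in seg.segments:
            s.v_abs += rng.normal(0, 1.5, s.v_abs.size)
        avg = average_cycles(seg.segments, proto)
        pre = (avg.t >= -proto.baseline_s) & (avg.t < 0)
        assert abs(avg.v_rel[pre].mean()) < 0.5

    def test_nonpositive_baseline_is_an_error(self):
        t = np.arange(-10, 81) / 2.0
        seg = [CycleSegment(t=t, v_abs=np.zeros_like(t), onset_s=20.0)]
        with pytest.raises(ValueError, match="baseline"):
            average_cycles(seg, PROTO)

    def test_ten_cycle_averaging_suppresses_noise(self, rng):
        """Zero-mean per-cycle noise of 3% shrinks by ~sqrt(10) on averaging."""
        p = SecondOrderParams(K=15, Tv=0.0, omega=0.2, xi=0.4)
        series, events, proto = _series_with_cycles(
            response=lambda tt: step_response(p, tt))
        seg = segment_cycles(series, events, proto)
        truth = average_cycles([s for s in seg.segments], proto).v_rel
        for s in seg.segments:
            s.v_abs = s.v_abs + 40.0 * rng.normal(0, 0.03, s.v_abs.size)
        noisy = average_cycles(seg.segments, proto).v_rel
        rms = np.sqrt(np.mean((noisy - truth) ** 2))
        assert rms <= 1.1


class TestComputeOvershoot:
    def _resp(self, t, v_rel, baseline=30.0):
        return AveragedResponse(t=t, v_rel=v_rel, baseline_abs=baseline,
                                n_cycles_used=10)

    def test_printed_formula_arithmetic(self):
        # baseline 30 cm/s rising to max 39 cm/s -> 100*(39-30)/30 = 30%
        t = np.arange(-10, 81) / 2.0
        v_abs = np.where(t > 0, 39.0, 30.0)
        v_rel = 100 * (v_abs / 30.0 - 1)
        assert compute_overshoot(self._resp(t, v_rel)) == pytest.approx(30.0)

    def test_flat_curve_has_zero_overshoot(self):
        t = np.arange(-10, 81) / 2.0
        assert compute_overshoot(self._resp(t, np.zeros_like(t))) == 0.0

    def test_invariant_to_velocity_rescaling(self):
        resp = lambda tt: 18 * (1 - np.exp(-tt / 4))
        series, events, proto = _series_with_cycles(response=resp)
        scaled = UniformSeries(series.t0, series.fs, 3.7 * series.values)
        o1 = compute_overshoot(average_cycles(
            segment_cycles(series, events, proto).segments, proto))
        o2 = compute_overshoot(average_cycles(
            segment_cycles(scaled, events, proto).segments, proto))
        assert o1 == pytest.approx(o2, rel=1e-12)

    def test_end_to_end_noiseless_overshoot_matches_analytic_peak(
            self, clean_session):
        # K=15, xi=0.4, Tv=0: peak = K(1 + exp(-pi*xi/sqrt(1-xi^2))) = 18.81
        rec, events = clean_session
        res = analyze_nvc(rec, events)
        expected = 15.0 * (1 + np.exp(-np.pi * 0.4 / np.sqrt(1 - 0.16)))
        assert res.overshoot_pct == pytest.approx(expected, abs=0.2)
        # the MCA control carries only the small non-specific response
        assert res.mca_overshoot_pct < 4.0
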