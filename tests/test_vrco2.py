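"""CO2 vasoreactivity slope, stage means, and variability band power."""

import numpy as np
import pytest

from nvckit.pipeline import analyze_vrco2
from nvckit.sos import SecondOrderParams
from nvckit.synth import SubjectTruth, simulate_vrco2_recording
from nvckit.vrco2 import StageSummary, band_power, stage_means, vrco2_slope


def _stage(name, etco2, rel):
    return StageSummary(stage=name, etco2_mean=etco2, cbfv_mean=rel * 0.3,
                        cbfv_rel=rel)


def _truth(slope=1.4, noise=0.0):
    return SubjectTruth(group="control",
                        sos=SecondOrderParams(15, 0.0, 0.2, 0.5),
                        vrco2_slope_true=slope, noise_sd_pct=noise,
                        artifact_rate=0.0)


class TestVrco2Slope:
    COLLINEAR = [_stage("vr_hyperventilation", 30.0, 85.0),
                 _stage("vr_baseline", 38.0, 100.0),
                 _stage("vr_hypercapnia", 46.0, 115.0)]

    def test_exact_on_collinear_points(self):
        res = vrco2_slope(self.COLLINEAR)
        assert res.slope == pytest.approx(30.0 / 16.0)  # 1.875 %/mmHg
        assert res.r2 == pytest.approx(1.0)

    def test_invariant_to_stage_order(self):
        res1 = vrco2_slope(self.COLLINEAR)
        res2 = vrco2_slope(list(reversed(self.COLLINEAR)))
        assert res1.slope == pytest.approx(res2.slope, rel=1e-12)

    def test_flat_cbfv_gives_zero_slope(self):
        stages = [_stage("vr_hyperventilation", 30, 100),
                  _stage("vr_baseline", 38, 100),
                  _stage("vr_hypercapnia", 46, 100)]
        assert vrco2_slope(stages).slope == 0.0

    def test_degenerate_etco2_rejected(self):
        stages = [_stage("vr_hyperventilation", 38, 85),
                  _stage("vr_baseline", 38, 100),
                  _stage("vr_hypercapnia", 38, 115)]
        with pytest.raises(ValueError, match="degenerate"):
            vrco2_slope(stages)

    def test_wrong_stage_count_rejected(self):
        with pytest.raises(ValueError, match="three"):
            vrco2_slope(self.COLLINEAR[:2])


@pytest.fixture(scope="module")
def session():
    return simulate_vrco2_recording(_truth(), seed=3, fs=200.0)


class TestStageMeans:

    def test_etco2_plateaus_recovered(self, session):
        rec, events = session
        stages = {s.stage: s for s in stage_means(rec, events)}
        assert stages["vr_baseline"].etco2_mean == pytest.approx(38.0, abs=0.2)
        assert stages["vr_hypercapnia"].etco2_mean == pytest.approx(46.0, abs=0.2)
        assert stages["vr_hyperventilation"].etco2_mean == pytest.approx(30.0, abs=0.2)

    def test_hypercapnic_rise_in_protocol_band(self, session):
        """The CO2 challenge raises EtCO2 7-10 mmHg above baseline."""
        rec, events = session
        stages = {s.stage: s for s in stage_means(rec, events)}
        rise = stages["vr_hypercapnia"].etco2_mean - stages["vr_baseline"].etco2_mean
        assert 7.0 <= rise <= 10.0

    def test_baseline_stage_is_reference(self, session):
        rec, events = session
        stages = {s.stage: s for s in stage_means(rec, events)}
        assert stages["vr_baseline"].cbfv_rel == 100.0

    def test_unreactive_subject_has_flat_relative_cbfv(self):
        rec, events = simulate_vrco2_recording(_truth(slope=0.0), seed=4,
                                               fs=200.0)
        for s in stage_means(rec, events):
            assert s.cbfv_rel == pytest.approx(100.0, abs=0.5)

    def test_missing_stage_named_in_error(self, session):
        rec, events = session
        from nvckit.io import EventList
        partial = EventList([e for e in events
                             if e.label != "vr_hyperventilation"])
        with pytest.raises(ValueError, match="vr_hyperventilation"):
            stage_means(rec, partial)

    def test_rescaling_velocity_channel_leaves_slope_unchanged(self, session):
        rec, events = session
        base = analyze_vrco2(rec, events).slope
        rec.channels["PCA"] = 2.3 * rec["PCA"]
        scaled = analyze_vrco2(rec, events).slope
        assert scaled == pytest.approx(base, rel=1e-9)


class TestEndToEndSlope:
    def test_noiseless_recovery(self):
        rec, events = simulate_vrco2_recording(_truth(slope=1.4), seed=5,
                                               fs=200.0)
        res = analyze_vrco2(rec, events)
        assert res.slope == pytest.approx(1.40, abs=0.01)
        assert res.r2 > 0.999

    def test_null_slope_with_noise(self):
        rec, events = simulate_vrco2_recording(_truth(slope=0.0, noise=2.0),
                                               seed=6, fs=200.0)
        assert abs(analyze_vrco2(rec, events).slope) < 0.05

    def test_noisy_recovery_within_tolerance(self):
        rec, events = simulate_vrco2_recording(_truth(slope=1.4, noise=3.0),
                                               seed=7, fs=200.0)
        assert analyze_vrco2(rec, events).slope == pytest.approx(1.4, abs=0.2)


class TestBandPower:
    FS = 4.0

    def test_sinusoid_power_parseval(self):
        t = np.arange(0, 300, 1 / self.FS)
        a = 2.0
        x = a * np.sin(2 * np.pi * 0.1 * t)
        bp = band_power(x, self.FS, (0.02, 0.5))
        assert bp.power == pytest.approx(a * a / 2, rel=0.05)

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(0, 300, 1 / self.FS)
        x = 2.0 * np.sin(2 * np.pi * 1.2 * t)  # above the 0.5 Hz band edge
        bp = band_power(x, self.FS, (0.02, 0.5))
        assert bp.power < 0.01 * 2.0
    def test_white_noise_total_power_is_variance(self, rng):
        sigma = 1.5
        x = rng.normal(0, sigma, 4096)
        bp = band_power(x, self.FS, (0.0, self.FS / 2))
        assert bp.power == pytest.approx(sigma * sigma, rel=0.10)

    def test_additive_over_disjoint_bands(self):
        t = np.arange(0, 400, 1 / self.FS)
        x = (1.0 * np.sin(2 * np.pi * 0.06 * t)
             + 0.5 * np.sin(2 * np.pi * 0.31 * t))
        total = band_power(x, self.FS, (0.02, 0.5)).power
        lo = band_power(x, self.FS, (0.02, 0.15)).power
        hi = band_power(x, self.FS, (0.16, 0.5)).power
        assert lo + hi == pytest.approx(total, rel=0.02)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.zeros(1000), self.FS, (0.1, 3.0))
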