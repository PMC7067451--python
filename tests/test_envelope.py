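"""Unit tests for change-point breath segmentation and envelope rebuild."""

from __future__ import annotations

import numpy as np
import pytest

import csrdemod as cd
from csrdemod.envelope import _pelt, default_penalty, detrend

from _oracles import dp_segmentation, match_events


def triangle_train(period_s: float = 4.0, duration_s: float = 60.0, fs: float = 25.0):
    t = np.arange(0.0, duration_s, 1.0 / fs)
    x = 2.0 * np.abs((t / period_s) % 1.0 - 0.5)
    return cd.TimeSeries(x, fs)


class TestDetectChangePoints:
    def test_piecewise_linear_breaks_found_exactly(self):
        # four exact slope breaks, no noise
        fs = 10.0
        knots_t = [0.0, 3.0, 6.0, 8.0, 11.0, 15.0]
        knots_v = [0.0, 3.0, 1.0, 4.0, -1.0, 2.0]
        t = np.arange(0.0, 15.0, 1.0 / fs)
        x = np.interp(t, knots_t, knots_v)
        cps = cd.detect_change_points(cd.TimeSeries(x, fs), beta=1e-6)
        for knot in knots_t[1:-1]:
            assert np.min(np.abs(cps - knot)) <= 1.0 / fs

    def test_constant_signal_has_no_change_points(self):
        ts = cd.TimeSeries(np.ones(200), 10.0)
        assert len(cd.detect_change_points(ts, beta=0.5)) == 0

    def test_triangular_train_peaks_and_troughs(self):
        ts = triangle_train()
        cps = cd.detect_change_points(ts)
        # interior turning points: 15 peaks (t=2,6,..,58) + 14 troughs
        truth = np.sort(np.concatenate([np.arange(2.0, 60, 4), np.arange(4.0, 58, 4)]))
        assert len(cps) == len(truth)
        assert np.max(np.abs(cps - truth)) <= 1.0 / ts.sampling_rate

    def test_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(11)
        pieces = [rng.normal(m, 0.1, 150) for m in (0.0, 2.0, -1.0, 1.0)]
        x = np.concatenate(pieces)
        beta = default_penalty(x)
        assert _pelt(x, beta, 3) == dp_segmentation(x, beta, 3)

    def test_matches_dp_oracle_on_breath_signal(self, breath_recording):
        x = detrend(breath_recording.signal).values[:2000]
        beta = default_penalty(x)
        assert _pelt(x, beta, 3) == dp_segmentation(x, beta, 3)

    def test_empty_and_short_signals_rejected(self):
        with pytest.raises(ValueError):
            cd.detect_change_points(cd.TimeSeries(np.array([1.0, 2.0]), 1.0))


class TestExtractBreaths:
    def test_regular_sinusoid_one_peak_per_period(self):
        fs = 25.0
        t = np.arange(0.0, 60.0, 1.0 / fs)
        ts = cd.TimeSeries(-np.cos(2 * np.pi * 0.25 * t), fs)
        cps = cd.detect_change_points(ts)
        seg = cd.extract_breaths(ts, cps)
        assert len(seg.peak_times) == 15
        np.testing.assert_allclose(np.diff(seg.peak_times), 4.0, atol=0.12)

    def test_low_slope_drift_section_discarded(self):
        fs = 25.0
        t = np.arange(0.0, 40.0, 1.0 / fs)
        breath = -np.cos(2 * np.pi * 0.25 * t)
        drift = 1e-4 * np.arange(int(20 * fs)) / fs  # flat drift, slope 1e-4
        x = np.concatenate([breath, drift + breath[-1]])
        ts = cd.TimeSeries(x, fs)
        seg = cd.extract_breaths(ts, cd.detect_change_points(ts))
        # all peaks belong to the breath train; none in the drift
        assert (seg.peak_times < 40.5).all()
        assert len(seg.peak_times) == 10

    def test_short_spike_rejected(self):
        fs = 50.0
        t = np.arange(0.0, 60.0, 1.0 / fs)
        x = -np.cos(2 * np.pi * 0.25 * t)
        # spike sits mid-limb, away from any true peak (peaks at 2, 6, ...)
        spike = (t > 31.5) & (t < 32.0)
        x = x + 2.0 * spike * np.sin(np.pi * (t - 31.5) / 0.5)
        ts = cd.TimeSeries(x, fs)
        seg = cd.extract_breaths(ts, cd.detect_change_points(ts))
        # the 0.5-s spike must not contribute an extra peak
        assert len(seg.peak_times) == 15

    def test_idempotent_on_own_output(self, mild_csr_signal):
        ts = mild_csr_signal
        cps = cd.detect_change_points(ts)
        first = cd.extract_breaths(ts, cps)
        second = cd.extract_breaths(ts, first.change_points)
        np.testing.assert_array_equal(first.peak_times, second.peak_times)
        np.testing.assert_array_equal(first.peak_amps, second.peak_amps)

    def test_too_few_change_points_gives_empty_peaks(self):
        ts = cd.TimeSeries(np.linspace(0, 1, 100), 10.0)
        seg = cd.extract_breaths(ts, np.array([]))
        assert len(seg.peak_times) == 0


class TestDetectGaps:
    def test_spec_gap_example(self):
        peaks = np.array([0.0, 4.0, 8.0, 12.0, 16.0, 36.0])
        assert cd.detect_gaps(peaks) == [(16.0, 36.0)]

    def test_regular_peaks_no_gaps(self):
        assert cd.detect_gaps(np.arange(0.0, 60.0, 4.0)) == []

    def test_boundary_spacing_is_strict(self):
        # spacing exactly 3x the median is NOT a gap
        peaks = np.array([0.0, 4.0, 8.0, 12.0, 24.0, 28.0, 32.0])
        assert cd.detect_gaps(peaks) == []

    def test_under_three_peaks_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert cd.detect_gaps(np.array([0.0, 4.0])) == []
        assert any("3 peaks" in r.message for r in caplog.records)


class TestReconstructEnvelope:
    def test_constant_peaks_give_unit_envelope(self):
        seg = cd.BreathSegmentation(
            change_points=np.array([]),
            peak_times=np.arange(0.0, 60.0, 4.0),
            peak_amps=np.ones(15),
        )
        env = cd.reconstruct_envelope(seg, t_end=60.0)
        np.testing.assert_allclose(env.series.values, 1.0)

    def test_gap_interior_forced_to_zero(self):
        seg = cd.BreathSegmentation(
            change_points=np.array([]),
            peak_times=np.array([0.0, 4.0, 8.0, 12.0, 16.0, 36.0, 40.0]),
            peak_amps=np.ones(7),
            gaps=((16.0, 36.0),),
        )
        env = cd.reconstruct_envelope(seg, t_end=40.0, fs_env=1.0)
        t = env.series.times
        inside = (t > 16.0) & (t < 36.0)
        assert (env.series.values[inside] == 0.0).all()
        assert (env.series.values[~inside] > 0.0).all()

    def test_envelope_tracks_analytic_model(self, mild_csr_signal):
        seg, env = cd.compute_envelope(mild_csr_signal)
        true = 1.0 + 0.5 * np.cos(2 * np.pi * 0.02 * seg.peak_times)
        assert np.max(np.abs(seg.peak_amps - true)) < 0.05

    def test_insufficient_peaks_raise(self):
        seg = cd.BreathSegmentation(
            change_points=np.array([]), peak_times=np.array([1.0]),
            peak_amps=np.array([1.0]),
        )
        with pytest.raises(ValueError, match="insufficient breaths"):
            cd.reconstruct_envelope(seg, t_end=10.0)


class TestBreathRecallPrecision:
    @pytest.mark.parametrize("noise,jitter", [(0.0, 0.1), (0.05, 0.1)])
    def test_recall_precision_on_simulated_recordings(self, noise, jitter):
        schedule = (
            cd.Segment(0.0, 120.0, cd.CSRParams(h=0.0, f_m=0.01)),
            cd.Segment(120.0, 420.0, cd.CSRParams(h=0.5, f_m=0.01)),
        )
        rec = cd.build_recording(
            schedule, fs=25.0, noise_sd=noise, breath_jitter=jitter, seed=5,
            carrier="breath",
        )
        seg, _ = cd.compute_envelope(rec.signal)
        tp, fn, fp = match_events(seg.peak_times, rec.breath_peaks, tol_s=0.5)
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95
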