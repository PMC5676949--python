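"""ECG chain: epoching, notch preprocessing, envelope flattening, R-peaks."""

import numpy as np
import pytest

import ictalhr as ih
from ictalhr.ecg import (EcgEpoch, detect_r_peaks, flatten, preprocess_epoch,
                         segment_epochs)
from ictalhr.types import WaveformRecord

from conftest import recovery_fraction


def brute_force_flatten(x: np.ndarray, w: int):
    """O(n*w) centred truncated-window sliding max/min oracle."""
    h = w // 2
    n = x.size
    U = np.array([x[max(0, i - h):min(n, i + h + 1)].max() for i in range(n)])
    L = np.array([x[max(0, i - h):min(n, i + h + 1)].min() for i in range(n)])
    return U, L


class TestSegmentation:
    def test_exact_multiple(self):
        rec = WaveformRecord(np.zeros(180 * 250), 250.0, "ecg")
        eps = segment_epochs(rec)
        assert len(eps) == 3
        assert all(e.samples.size == 15000 for e in eps)

    def test_trailing_partial_epoch(self):
        rec = WaveformRecord(np.zeros(150 * 250), 250.0, "ecg")
        eps = segment_epochs(rec)
        assert [e.epoch_length for e in eps] == [60.0, 60.0, 30.0]
        # concatenation reconstructs the record
        assert sum(e.samples.size for e in eps) == rec.n_samples

    def test_short_record_single_epoch(self, caplog):
        rec = WaveformRecord(np.zeros(5 * 250), 250.0, "ecg")
        with caplog.at_level("WARNING"):
            eps = segment_epochs(rec)
        assert len(eps) == 1 and eps[0].epoch_length == 5.0
        assert any("trailing epoch" in r.message for r in caplog.records)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            segment_epochs(WaveformRecord(np.empty(0), 250.0, "ecg"))


class TestPreprocess:
    def test_constant_becomes_zero(self):
        ep = EcgEpoch(np.full(15000, 3.7), 250.0, 0.0)
        out = preprocess_epoch(ep)
        assert np.max(np.abs(out.samples)) < 1e-9

    def test_50hz_attenuated(self):
        t = np.arange(15000) / 250.0
        ep = EcgEpoch(np.sin(2 * np.pi * 50.0 * t), 250.0, 0.0)
        out = preprocess_epoch(ep)
        rms_in = np.sqrt(np.mean(ep.samples ** 2))
        rms_out = np.sqrt(np.mean(out.samples ** 2))
        assert rms_out <= 0.1 * rms_in

    def test_qrs_band_preserved(self):
        t = np.arange(15000) / 250.0
        ep = EcgEpoch(np.sin(2 * np.pi * 10.0 * t), 250.0, 0.0)
        out = preprocess_epoch(ep)
        rms_in = np.sqrt(np.mean(ep.samples ** 2))
        rms_out = np.sqrt(np.mean(out.samples ** 2))
        assert rms_out >= 0.89 * rms_in

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            preprocess_epoch(EcgEpoch(np.zeros(500), 100.0, 0.0))


class TestFlatten:
    def test_constant_gives_zero_f(self):
        out = flatten(EcgEpoch(np.full(1000, 2.0), 250.0, 0.0))
        assert np.all(out.F == 0.0)

    def test_square_wave_faster_than_window(self):
        # +/-A alternation with period shorter than the window: every
        # (truncated) window sees both levels, so F = 2A everywhere
        x = np.tile(np.repeat([1.0, -1.0], 5), 100)
        out = flatten(EcgEpoch(x, 250.0, 0.0), envelope_window=0.1)
        assert np.allclose(out.F, 2.0)
        U, L = brute_force_flatten(x, 25)
        np.testing.assert_array_equal(out.F, U - L)

    def test_impulse_spreads_over_window(self):
        x = np.zeros(200)
        x[100] = 1.0
        out = flatten(EcgEpoch(x, 250.0, 0.0), envelope_window=0.1)
        w = 25
        assert np.sum(out.F == 1.0) == w
        assert np.all(out.F[100 - w // 2:100 + w // 2 + 1] == 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        out = flatten(EcgEpoch(x, 250.0, 0.0), envelope_window=0.1)
        U, L = brute_force_flatten(x, 25)
        np.testing.assert_array_equal(out.U, U)
        np.testing.assert_array_equal(out.L, L)
        np.testing.assert_array_equal(out.F, U - L)

    def test_envelope_sandwich_invariants(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        out = flatten(EcgEpoch(x, 250.0, 0.0))
        assert np.all(out.F >= 0)
        assert np.all(out.U >= x) and np.all(x >= out.L)

    def test_window_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            flatten(EcgEpoch(np.zeros(10), 250.0, 0.0), envelope_window=1.0)


class TestRPeaks:
    def _detect(self, rec):
        ep = EcgEpoch(rec.samples, rec.fs, 0.0)
        pre = preprocess_epoch(ep)
        return detect_r_peaks(flatten(pre), pre)

    def test_flat_epoch_empty(self):
        ep = EcgEpoch(np.zeros(15000), 250.0, 0.0)
        beats = detect_r_peaks(flatten(ep), ep)
        assert len(beats) == 0

    def test_clean_60bpm_beat_count_and_timing(self):
        cfg = ih.SimConfig(duration=60.0, baseline_hr=60.0, hr_jitter_sd=0.0)
        beats_gt, _ = ih.generate_rr_series(cfg)
        rec = ih.synthesize_ecg(beats_gt, 250.0, 60.0)
        beats = self._detect(rec)
        assert 59 <= len(beats) <= 61
        assert recovery_fraction(beats_gt[1:-1], beats.times, 0.010) == 1.0

    def test_powerline_interference_removed_by_preprocessing(self):
        cfg = ih.SimConfig(duration=60.0, baseline_hr=60.0, hr_jitter_sd=0.0)
        beats_gt, _ = ih.generate_rr_series(cfg)
        rec = ih.synthesize_ecg(beats_gt, 250.0, 60.0)
        noisy = ih.inject_artifacts(
            rec, ih.ArtifactSpec("powerline_50hz", ((0.0, 60.0),),
                                 amplitude=0.3))
        assert len(self._detect(noisy)) == len(self._detect(rec))

    def test_amplitude_invariance(self):
        cfg = ih.SimConfig(duration=120.0, baseline_hr=75.0, hr_jitter_sd=2.0,
                           seed=6)
        ecg, _, _ = ih.generate_record(cfg)
        for k in (0.01, 5.0):
            scaled = WaveformRecord(k * ecg.samples, ecg.fs, "ecg")
            np.testing.assert_array_equal(ih.extract_beats(scaled).times,
                                          ih.extract_beats(ecg).times)

    def test_inverted_lead(self):
        cfg = ih.SimConfig(duration=120.0, baseline_hr=70.0, hr_jitter_sd=0.0)
        ecg, _, truth = ih.generate_record(cfg)
        flipped = WaveformRecord(-ecg.samples, ecg.fs, "ecg")
        beats = ih.extract_beats(flipped)
        assert recovery_fraction(truth.beat_times[1:-1], beats.times,
                                 0.010) >= 0.99


class TestExtractHrv:
    def test_median_rate_matches_baseline(self):
        cfg = ih.SimConfig(duration=600.0, baseline_hr=70.0,
                           hr_jitter_sd=0.0)
        ecg, _, _ = ih.generate_record(cfg)
        rate = ih.extract_hrv(ecg)
        assert abs(np.median(rate.rates) - 70.0) <= 1.0

    def test_ictal_ramp_peak_rate(self):
        ev = ih.SimSeizureEvent(onset=250.0, duration=60.0, delta_hr=30.0,
                                ramp_time=30.0)
        cfg = ih.SimConfig(duration=600.0, baseline_hr=70.0,
                           hr_jitter_sd=0.0, seizures=(ev,))
        ecg, _, _ = ih.generate_record(cfg)
        rate = ih.extract_hrv(ecg)
        assert abs(np.max(rate.rates) - 100.0) <= 3.0

    def test_boundary_beats_deduplicated(self):
        cfg = ih.SimConfig(duration=61.0, baseline_hr=70.0, hr_jitter_sd=2.0,
                           seed=8)
        ecg, _, truth = ih.generate_record(cfg)
        beats = ih.extract_beats(ecg)
        assert np.all(np.diff(beats.times) > 0.25)  # no epoch-edge doubles
        assert recovery_fraction(truth.beat_times[1:-1], beats.times,
                                 0.010) >= 0.99

    def test_rate_reciprocity(self):
        cfg = ih.SimConfig(duration=300.0, hr_jitter_sd=3.0, seed=4)
        ecg, _, _ = ih.generate_record(cfg)
        beats = ih.extract_beats(ecg)
        rate = ih.beats_to_rate(beats)
        # every emitted sample satisfies r * dt = 60 exactly
        idx = np.searchsorted(beats.times, rate.times)
        dt = rate.times - beats.times[idx - 1]
        np.testing.assert_allclose(rate.rates * dt, 60.0, rtol=1e-12)


class TestBeatsToRate:
    def test_uniform_beats(self):
        r = ih.beats_to_rate(ih.BeatSeries(np.array([0.0, 1, 2, 3]), "ecg"))
        np.testing.assert_allclose(r.rates, [60.0, 60.0, 60.0])
        np.testing.assert_allclose(r.times, [1.0, 2.0, 3.0])

    def test_mixed_gaps(self):
        r = ih.beats_to_rate(ih.BeatSeries(np.array([0.0, 1.0, 1.5]), "ecg"))
        np.testing.assert_allclose(r.rates, [60.0, 120.0])

    def test_dropout_gap_guarded(self):
        r = ih.beats_to_rate(ih.BeatSeries(np.array([0.0, 1.0, 4.0, 5.0]),
                                           "ecg"))
        np.testing.assert_allclose(r.times, [1.0, 5.0])

    def test_single_beat_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            r = ih.beats_to_rate(ih.BeatSeries(np.array([1.0]), "ecg"))
        assert len(r) == 0
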