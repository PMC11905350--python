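"""Filtering, STFT, line-noise fill and two-stage outlier rejection."""

import numpy as np
import pytest
from scipy import signal as sps

import optoephys as oe
from optoephys.filters import design_bandpass
from optoephys.lfp import (
    load_recording_text,
    load_spectrogram_h5,
    save_spectrogram_h5,
)
from optoephys.synthetic import write_lfp_text

from conftest import short_lfp_config


def tone_recording(freq_hz, fs=1000.0, dur=20.0, amp=1.0, offset=0.0):
    t = np.arange(0, dur, 1 / fs)
    return oe.LFPRecording(["BLA"], fs, (amp * np.sin(2 * np.pi * freq_hz * t) + offset)[None, :])


def flat_spectrogram(value=1.0, n_t=20, n_f=101, df=1.0, dt=1.0):
    return oe.Spectrogram(
        times_s=dt * (0.5 + np.arange(n_t)),
        freqs_hz=df * np.arange(n_f),
        power=np.full((n_t, n_f), value),
        window_s=1.0,
        overlap_frac=0.5,
        channel_label="BLA",
    )


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = tone_recording(20.0)
        out = oe.bandpass(rec, 1.0, 250.0)
        interior = slice(2000, -2000)
        ratio = out.data[0, interior].std() / rec.data[0, interior].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_out_of_band_attenuation_matches_design(self):
        # oracle: attenuation at 0.1 Hz read off the designed filter response
        sos = design_bandpass(1.0, 250.0, 1000.0)
        w, h = sps.sosfreqz(sos, worN=[0.1], fs=1000.0)
        design_db = -20 * np.log10(np.abs(h[0]))
        assert design_db >= 20.0 / 2  # single pass; filtfilt doubles it

        rec = tone_recording(0.1, dur=60.0)
        out = oe.bandpass(rec, 1.0, 250.0)
        interior = slice(10000, -10000)
        emp_db = -20 * np.log10(
            out.data[0, interior].std() / rec.data[0, interior].std()
        )
        assert emp_db >= 20.0
        assert emp_db == pytest.approx(2 * design_db, abs=3.0)

    def test_dc_removed(self):
        rec = tone_recording(20.0, offset=5.0)
        out = oe.bandpass(rec, 3.0, 300.0)
        assert abs(out.data[0, 2000:-2000].mean()) < 0.01

    def test_band_outside_nyquist(self):
        with pytest.raises(oe.ParameterError):
            oe.bandpass(tone_recording(20.0), 1.0, 600.0)


class TestSTFT:
    def test_tone_peaks_at_drive_bin(self):
        spec = oe.compute_stft(tone_recording(20.0), window_s=5.0)
        assert np.all(spec.freqs_hz[np.argmax(spec.power, axis=1)] == 20.0)

    def test_window_sets_frequency_resolution(self):
        spec = oe.compute_stft(tone_recording(20.0), window_s=1.0)
        assert np.allclose(np.diff(spec.freqs_hz), 1.0)
        spec5 = oe.compute_stft(tone_recording(20.0), window_s=5.0)
        assert np.allclose(np.diff(spec5.freqs_hz), 0.2)

    def test_white_noise_spectrum_flat(self, rng):
        x = rng.standard_normal(250 * 300)
        rec = oe.LFPRecording(["BLA"], 250.0, x[None, :])
        spec = oe.compute_stft(rec, window_s=1.0)
        mean_by_freq = spec.power[:, 1:-1].mean(axis=0)  # drop DC and Nyquist
        cv = mean_by_freq.std() / mean_by_freq.mean()
        assert cv < 0.2

    def test_power_is_quadratic_in_amplitude(self):
        s1 = oe.compute_stft(tone_recording(20.0, amp=1.0), window_s=1.0)
        s2 = oe.compute_stft(tone_recording(20.0, amp=2.0), window_s=1.0)
        np.testing.assert_allclose(s2.power, 4.0 * s1.power, rtol=1e-9)

    def test_too_short_recording(self):
        with pytest.raises(oe.DataError):
            oe.compute_stft(tone_recording(20.0, dur=2.0), window_s=5.0)


class TestLineNoise:
    def test_ridge_replaced_by_nearest_neighbour(self):
        spec = flat_spectrogram()
        spec.power[:, 60] = 10.0  # 60 Hz ridge
        out = oe.remove_line_noise(spec)
        assert np.all(out.power[:, 59:62] == 1.0)
        untouched = np.delete(np.arange(101), [59, 60, 61])
        np.testing.assert_array_equal(out.power[:, untouched], spec.power[:, untouched])

    def test_no_bins_in_band_warns_and_passes_through(self):
        spec = flat_spectrogram(n_f=12, df=7.0)  # 0,7,...,77 Hz: none in 59-61
        with pytest.warns(UserWarning, match="no frequency bins"):
            out = oe.remove_line_noise(spec)
        np.testing.assert_array_equal(out.power, spec.power)

    def test_flat_spectrogram_unchanged(self):
        out = oe.remove_line_noise(flat_spectrogram())
        assert np.all(out.power == 1.0)


class TestOutlierRejection:
    def test_stage1_flags_constructed_deviation(self):
        # 1000 bins at 1.0 with one at 50: the spike exceeds mean + 4 SD of
        # the series (direct computation), everything else stays
        n = 1000
        power = np.ones((n, 5))
        power[300] = 50.0
        series = power.mean(axis=1)
        assert series[300] > series.mean() + 4 * series.std()
        spec = oe.Spectrogram(
            times_s=np.arange(n, dtype=float), freqs_hz=np.arange(5, dtype=float),
            power=power, window_s=1.0, overlap_frac=0.0,
        )
        out = oe.detect_outliers(spec)
        assert out.outlier_mask[300]
        assert out.outlier_mask.sum() == 1
        np.testing.assert_array_equal(out.power[300], np.ones(5))

    def test_constant_spectrogram_untouched(self):
        spec = flat_spectrogram(n_t=400)
        out = oe.detect_outliers(spec)
        assert out.outlier_mask.sum() == 0
        np.testing.assert_array_equal(out.power, spec.power)

    def test_short_input_runs_stage1_only(self):
        spec = flat_spectrogram(n_t=20)
        with pytest.warns(UserWarning, match="sliding-window stage skipped"):
            oe.detect_outliers(spec)

    def test_artifact_recovery_on_synthetic_lfp(self):
        art_times = (60.0, 150.0, 290.0, 420.0, 555.0)
        cfg = short_lfp_config(
            seed=11, duration_s=620.0, stim_schedule=[], stim_amp=0.0,
            artifact_times_s=art_times, artifact_amp=150.0,
        )
        rec, _ = oe.generate_lfp_pair(cfg)
        rec = oe.bandpass(rec, 1.0, 100.0)
        spec = oe.compute_stft(rec, "BLA", window_s=5.0)
        out = oe.detect_outliers(spec)
        # a bin "contains" the artifact when its own hop-length span does
        half_hop = 5.0 * (1 - 0.5) / 2  # hop = window * (1 - overlap)
        is_art = np.zeros(spec.times_s.size, dtype=bool)
        for t0 in art_times:
            is_art |= (spec.times_s + half_hop > t0) & (spec.times_s - half_hop < t0 + 0.5)
        flagged = out.outlier_mask
        assert flagged[is_art].mean() >= 0.9
        assert flagged[~is_art].mean() < 0.01

    def test_cleaning_is_idempotent(self):
        cfg = short_lfp_config(
            seed=12, duration_s=620.0, stim_schedule=[], stim_amp=0.0,
            artifact_times_s=(100.0, 400.0), artifact_amp=150.0,
        )
        rec, _ = oe.generate_lfp_pair(cfg)
        rec = oe.bandpass(rec, 1.0, 100.0)
        once = oe.detect_outliers(oe.compute_stft(rec, "BLA", window_s=5.0))
        twice = oe.detect_outliers(once)
        series = once.mean_power_series()
        # stage-1 statistics recomputed on cleaned data flag nothing new
        assert np.sum(series > series.mean() + 4 * series.std()) == 0
        assert not np.any(twice.outlier_mask & ~once.outlier_mask & ~once.outlier_mask)

    def test_energy_preserved_without_artifacts(self):
        cfg = short_lfp_config(seed=13, duration_s=620.0, stim_schedule=[], stim_amp=0.0)
        rec, _ = oe.generate_lfp_pair(cfg)
        rec = oe.bandpass(rec, 1.0, 100.0)
        spec = oe.compute_stft(rec, "BLA", window_s=5.0)
        out = oe.detect_outliers(spec)
        assert abs(out.power.sum() - spec.power.sum()) / spec.power.sum() < 1e-3

    def test_all_flagged_is_error(self):
        # varying series with the threshold forced below every value
        power = np.arange(1.0, 5.0)[:, None] * np.ones((1, 3))
        s = oe.Spectrogram(
            times_s=np.arange(4.0), freqs_hz=np.arange(3.0), power=power,
            window_s=1.0, overlap_frac=0.0,
        )
        with pytest.raises(oe.DataError):
            oe.detect_outliers(s, global_k=-2.0)


class TestIO:
    def test_text_round_trip(self, tmp_path):
        rec, _ = oe.generate_lfp_pair(short_lfp_config(seed=1, duration_s=4.0,
                                                       stim_schedule=[], stim_amp=0.0))
        path = tmp_path / "rec.csv"
        write_lfp_text(rec, path)
        back = load_recording_text(path)
        assert back.channel_labels == ["BLA", "mPFC"]
        assert back.fs_hz == pytest.approx(rec.fs_hz, rel=1e-6)
        np.testing.assert_allclose(back.data, rec.data, atol=1e-5)

    def test_spectrogram_h5_round_trip(self, tmp_path):
        spec = flat_spectrogram()
        spec.outlier_mask[3] = True
        path = tmp_path / "spec.h5"
        save_spectrogram_h5(spec, path)
        back = load_spectrogram_h5(path)
        np.testing.assert_array_equal(back.power, spec.power)
        np.testing.assert_array_equal(back.outlier_mask, spec.outlier_mask)
        assert back.window_s == spec.window_s

    def test_edf_round_trip_against_mne(self, tmp_path):
        pytest.importorskip("mne")
        from optoephys.edf import write_edf

        rec, _ = oe.generate_lfp_pair(short_lfp_config(seed=2, duration_s=4.0,
                                                       stim_schedule=[], stim_amp=0.0))
        path = tmp_path / "rec.edf"
        write_edf(rec, path)
        back = oe.load_recording(path)
        assert back.channel_labels == rec.channel_labels
        assert back.fs_hz == rec.fs_hz
        # 16-bit quantization over the +/- few-hundred-uV range
        span = rec.data.max() - rec.data.min()
        assert np.max(np.abs(back.data - rec.data)) < span / 2**15
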