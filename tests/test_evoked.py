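"""Evoked-power quantification: band power, ratios, inclusion, Morse."""

import numpy as np
import pandas as pd
import pytest

import optoephys as oe
from optoephys.evoked import PowerRatioResult, results_to_frame

from conftest import SHORT_WINDOWS, short_lfp_config


def make_spec(power, dt=0.5, df=1.0):
    power = np.asarray(power, dtype=float)
    return oe.Spectrogram(
        times_s=dt * (0.5 + np.arange(power.shape[0])),
        freqs_hz=df * np.arange(power.shape[1]),
        power=power,
        window_s=1.0,
        overlap_frac=0.5,
        channel_label="BLA",
    )


def make_result(ratio, freq=20.0, repeat=1, channel="BLA"):
    return PowerRatioResult(channel, freq, repeat, ratio, 1.0, ratio)


class TestBandPower:
    def test_flat_spectrogram_returns_constant(self):
        spec = make_spec(np.full((40, 60), 3.7))
        assert oe.band_power(spec, 20.0, 1.0, (0.0, 10.0)) == pytest.approx(3.7)

    def test_ridge_plus_background_arithmetic(self):
        power = np.ones((10, 60))
        power[:, 20] = 10.0
        spec = make_spec(power)
        # band 19-21 Hz holds bins {19, 20, 21}: (10 + 1 + 1) / 3
        assert oe.band_power(spec, 20.0, 1.0) == pytest.approx(4.0)

    def test_one_second_bins_give_three_bin_band(self):
        rec, _ = oe.generate_lfp_pair(short_lfp_config(seed=0))
        spec = oe.compute_stft(rec, "BLA", window_s=1.0)
        in_band = (spec.freqs_hz >= 19.0) & (spec.freqs_hz <= 21.0)
        assert in_band.sum() == 3

    def test_stim_band_power_exceeds_baseline(self):
        cfg = short_lfp_config(seed=5)
        rec, prot = oe.generate_lfp_pair(cfg)
        spec = oe.compute_stft(rec, "BLA", window_s=1.0)
        e = next(iter(prot))
        stim = oe.band_power(spec, e.freq_hz, 1.0, (e.onset_s, e.offset_s))
        base = oe.band_power(spec, e.freq_hz, 1.0, (e.onset_s - 6.0, e.onset_s))
        assert stim > base

    def test_empty_band_is_error(self):
        spec = make_spec(np.ones((10, 30)))
        with pytest.raises(oe.DataError, match="band"):
            oe.band_power(spec, 100.0, 0.4)


class TestPowerRatio:
    def test_flat_spectrogram_ratio_is_exactly_one(self):
        spec = make_spec(np.full((200, 60), 2.0))
        prot = oe.StimProtocol([oe.StimEpoch(40.0, 60.0, 20.0)])
        res = oe.power_ratio(spec, prot, (0.0, 20.0), (-30.0, 0.0))
        assert res[0].ratio_minus_1 == 0.0

    def test_no_stim_ratio_scatters_around_zero(self):
        vals = []
        for seed in range(12):
            rec, prot = oe.generate_lfp_pair(
                short_lfp_config(seed=400 + seed, stim_amp=0.0)
            )
            spec = oe.compute_stft(rec, "BLA", window_s=1.0)
            res = oe.power_ratio(spec, prot, **SHORT_WINDOWS)
            vals.extend(r.ratio_minus_1 for r in res)
        vals = np.asarray(vals)
        # no-signal control: mean within 3 Monte-Carlo SDs of zero
        assert abs(vals.mean()) < 3 * vals.std(ddof=1)

    def test_ratio_monotone_in_stim_amplitude(self):
        wins = 0
        n = 40
        for seed in range(n):
            ratios = []
            for amp in (10.0, 20.0):
                sched = [oe.StimEpoch(10.0, 20.0, 20.0)]
                cfg = short_lfp_config(
                    seed=500 + seed, duration_s=25.0, stim_schedule=sched,
                    stim_amp=amp,
                )
                rec, prot = oe.generate_lfp_pair(cfg)
                spec = oe.compute_stft(rec, "BLA", window_s=1.0)
                res = oe.power_ratio(spec, prot, **SHORT_WINDOWS)
                ratios.append(res[0].ratio)
            if ratios[1] > ratios[0]:
                wins += 1
        assert wins / n >= 0.95

    def test_invariant_to_amplitude_scaling(self):
        cfg = short_lfp_config(seed=9)
        rec, prot = oe.generate_lfp_pair(cfg)
        rec2 = oe.LFPRecording(rec.channel_labels, rec.fs_hz, 7.0 * rec.data)
        r1 = oe.power_ratio(oe.compute_stft(rec, "BLA", window_s=1.0), prot, **SHORT_WINDOWS)
        r2 = oe.power_ratio(oe.compute_stft(rec2, "BLA", window_s=1.0), prot, **SHORT_WINDOWS)
        for a, b in zip(r1, r2):
            assert b.ratio == pytest.approx(a.ratio, rel=1e-9)

    def test_insufficient_baseline_skips_epoch(self):
        spec = make_spec(np.ones((100, 60)))
        prot = oe.StimProtocol([oe.StimEpoch(5.0, 15.0, 20.0)])
        with pytest.warns(UserWarning, match="insufficient pre-onset"):
            res = oe.power_ratio(spec, prot, (0.0, 10.0), (-30.0, 0.0))
        assert res == []


class TestInclusionFilter:
    def test_clear_outlier_excluded(self):
        # hand computation: mean 2.0, population SD 2.646, so the 9.0 entry
        # sits 2.65 SD out and is excluded while the rest stay within 0.42 SD
        ratios = [1.0, 1.0, 1.0, 1.0, 1.0, 1.1, 0.9, 9.0]
        arr = np.asarray(ratios)
        assert abs(arr[-1] - arr.mean()) > 2 * arr.std()
        results = [make_result(r, repeat=i + 1) for i, r in enumerate(ratios)]
        oe.inclusion_filter(results, k=2.0)
        assert [r.included for r in results] == [True] * 7 + [False]
        assert all(np.isfinite(r.deviation_score) for r in results)

    def test_single_outlier_in_small_group_cannot_reach_two_sd(self):
        # a lone extreme value among n inflates the SD it is judged by: its
        # deviation is bounded by (n-1)/sqrt(n) SD (1.79 at n=5), so the
        # 2 SD screen retains it no matter how large it is
        ratios = [1.0, 1.1, 0.9, 1.0, 9.0]
        results = [make_result(r, repeat=i + 1) for i, r in enumerate(ratios)]
        oe.inclusion_filter(results, k=2.0)
        assert all(r.included for r in results)
        assert max(abs(r.deviation_score) for r in results) < 2.0

    def test_equal_ratios_all_kept(self):
        results = [make_result(2.0, repeat=i + 1) for i in range(4)]
        oe.inclusion_filter(results)
        assert all(r.included for r in results)

    def test_infinite_k_keeps_all(self):
        results = [make_result(r, repeat=i + 1) for i, r in enumerate([1.0, 50.0])]
        oe.inclusion_filter(results, k=np.inf)
        assert all(r.included for r in results)

    def test_singleton_group_warns_and_passes(self):
        results = [make_result(1.0)]
        with pytest.warns(UserWarning, match="single repeat"):
            oe.inclusion_filter(results)
        assert results[0].included


class TestAverageRepeats:
    def test_mean_of_included(self):
        results = [make_result(2.0, repeat=1), make_result(4.0, repeat=2)]
        df = oe.average_repeats(results)
        assert df.loc[0, "mean_ratio"] == pytest.approx(3.0)
        assert df.loc[0, "n_included"] == 2

    def test_excluded_not_counted(self):
        results = [
            make_result(2.0, repeat=1),
            make_result(4.0, repeat=2),
            make_result(100.0, repeat=3),
        ]
        results[2].included = False
        df = oe.average_repeats(results)
        assert df.loc[0, "mean_ratio"] == pytest.approx(3.0)

    def test_no_included_reported_missing(self):
        results = [make_result(2.0)]
        results[0].included = False
        df = oe.average_repeats(results)
        assert np.isnan(df.loc[0, "mean_ratio"])
        assert df.loc[0, "n_included"] == 0


class TestPresentationOrder:
    def test_constructed_order_effect_visible(self):
        results = [
            make_result(amp, freq=20.0, repeat=pos)
            for pos, amp in [(1, 1.0), (2, 2.0), (3, 3.0)]
        ]
        df = oe.presentation_order_effect(results)
        row = df.iloc[0]
        assert row["position_1"] < row["position_2"] < row["position_3"]

    def test_single_repeat_single_column(self):
        df = oe.presentation_order_effect([make_result(1.5)])
        assert [c for c in df.columns if c.startswith("position_")] == ["position_1"]

    def test_order_independent_amplitudes_flat(self):
        # Monte-Carlo: per-position means agree within 3 SE when the
        # generator has no order effect
        per_pos = {1: [], 2: [], 3: []}
        for seed in range(25):
            rec, prot = oe.generate_lfp_pair(short_lfp_config(seed=700 + seed))
            spec = oe.compute_stft(rec, "BLA", window_s=1.0)
            for r in oe.power_ratio(spec, prot, **SHORT_WINDOWS):
                if r.freq_hz == 20.0:
                    per_pos[r.repeat_idx].append(r.ratio)
        means = {p: np.mean(v) for p, v in per_pos.items()}
        ses = {p: np.std(v, ddof=1) / np.sqrt(len(v)) for p, v in per_pos.items()}
        for p in (2, 3):
            assert abs(means[p] - means[1]) < 3 * np.hypot(ses[p], ses[1])


class TestMorse:
    def _tone(self, freq=20.0, amp=1.0, fs=500.0, dur=10.0):
        t = np.arange(0, dur, 1 / fs)
        return oe.LFPRecording(["BLA"], fs, (amp * np.sin(2 * np.pi * freq * t))[None, :])

    def test_tone_ridge_at_drive_frequency(self):
        spec = oe.morse_spectrogram(self._tone(), (5.0, 80.0))
        interior = slice(1000, -1000)
        ridge = spec.freqs_hz[np.argmax(spec.power[interior], axis=1)]
        np.testing.assert_allclose(ridge, 20.0, rtol=0.05)

    def test_linearity_in_amplitude(self):
        s1 = oe.morse_spectrogram(self._tone(amp=1.0), (5.0, 80.0))
        s2 = oe.morse_spectrogram(self._tone(amp=2.0), (5.0, 80.0))
        np.testing.assert_allclose(s2.power, 2.0 * s1.power, rtol=1e-9, atol=1e-12)

    def test_chirp_ridge_increases(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        from scipy.signal import chirp

        x = chirp(t, f0=5.0, f1=40.0, t1=20.0, method="linear")
        rec = oe.LFPRecording(["BLA"], fs, x[None, :])
        spec = oe.morse_spectrogram(rec, (3.0, 60.0), n_freqs=96)
        probe_times = np.linspace(2.0, 18.0, 9)
        idx = [np.argmin(np.abs(spec.times_s - pt)) for pt in probe_times]
        ridge = spec.freqs_hz[np.argmax(spec.power[idx], axis=1)]
        assert np.all(np.diff(ridge) > 0)

    def test_invalid_range(self):
        with pytest.raises(oe.ParameterError):
            oe.morse_spectrogram(self._tone(), (5.0, 400.0))


def test_results_frame_columns():
    df = results_to_frame([make_result(1.5)])
    assert {"channel", "freq_hz", "ratio", "ratio_minus_1", "included"} <= set(df.columns)
    assert isinstance(df, pd.DataFrame)
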