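"""MR-environment EEG cleaning operators."""

import numpy as np
import pytest
from scipy import signal

from eegfmri.containers import SensorRecording
from eegfmri.ica import fastica_deflation
from eegfmri.preprocess import (
    bandpass_filter,
    classify_artifact_ics,
    detect_bad_channels,
    detect_r_peaks,
    interpolate_channels,
    remove_bcg_artifact,
    remove_gradient_artifact,
    remove_ics_and_rereference,
)
from eegfmri.simulate import add_mr_artifacts
from eegfmri.source import band_bin_mask, stft_power


def _recording(data, fs=200.0, positions=None):
    n_ch = data.shape[0]
    if positions is None:
        ang = np.linspace(0, 2 * np.pi, n_ch, endpoint=False)
        positions = np.column_stack([60 * np.cos(ang), 60 * np.sin(ang),
                                     40 + 5 * np.sin(3 * ang)])
    return SensorRecording(data=data, fs=fs,
                           labels=[f"E{i:03d}" for i in range(n_ch)],
                           positions=positions)


def band_power(data, fs, lo, hi):
    p, f = stft_power(data, fs)
    return p[..., band_bin_mask(f, lo, hi), :].mean()


def artifact_band_power(data, fs, artifact):
    """Power restricted to the frequencies where the artifact lives."""
    f, p_art = signal.welch(artifact.mean(axis=0), fs=fs, nperseg=1024)
    sel = p_art > 0.001 * p_art.max()
    f2, p = signal.welch(data, fs=fs, nperseg=1024)
    return p[:, sel].sum()


class TestGradientRemoval:
    def test_periodic_artifact_removed_alpha_preserved(self, clean_subject):
        rec = clean_subject["rec"]
        dirty = add_mr_artifacts(
            rec, tr_s=2.0,
            amp_cfg={"gradient": 50.0, "bcg": 0.0, "eog": 0.0, "emg": 0.0},
            seed=8)
        artifact = dirty.data - rec.data
        out, _ = remove_gradient_artifact(dirty,
                                          n_avg_epochs=len(dirty.tr_markers),
                                          n_obs_pcs=3)
        before = artifact_band_power(dirty.data - rec.data, rec.fs, artifact)
        after = artifact_band_power(out.data - rec.data, rec.fs, artifact)
        assert 10 * np.log10(before / after) >= 40.0
        alpha_db = 10 * np.log10(band_power(out.data, rec.fs, 8, 13)
                                 / band_power(rec.data, rec.fs, 8, 13))
        assert abs(alpha_db) <= 1.0

    def test_zero_recording_stays_zero(self):
        rec = _recording(np.zeros((8, 4000)))
        rec.tr_markers = np.arange(0, 4000, 400)
        out, _ = remove_gradient_artifact(rec, n_avg_epochs=4, n_obs_pcs=0)
        assert np.max(np.abs(out.data)) < 1e-9

    def test_obs_improves_on_aas_for_drifting_amplitude(self, rng):
        fs = 200.0
        n = 16000
        tr = 400
        neural = 0.1 * rng.standard_normal((8, n))
        shape = signal.sawtooth(2 * np.pi * 5 * np.arange(tr) / tr)
        gains = 1.0 + 0.3 * np.sin(np.linspace(0, 3 * np.pi, n // tr))
        art = np.zeros((8, n))
        for j, m in enumerate(range(0, n, tr)):
            art[:, m:m + tr] = 50 * gains[j] * shape
        rec = _recording(neural + art, fs)
        rec.tr_markers = np.arange(0, n, tr)
        aas, _ = remove_gradient_artifact(rec, n_avg_epochs=10, n_obs_pcs=0)
        obs, _ = remove_gradient_artifact(rec, n_avg_epochs=10, n_obs_pcs=3)
        res_aas = np.sqrt(np.mean((aas.data - neural) ** 2))
        res_obs = np.sqrt(np.mean((obs.data - neural) ** 2))
        assert res_obs <= res_aas

    def test_missing_markers_rejected(self):
        rec = _recording(np.random.default_rng(0).standard_normal((8, 4000)))
        with pytest.raises(ValueError, match="gradient markers"):
            remove_gradient_artifact(rec, 4, 3)


class TestBcgRemoval:
    def test_jittered_bcg_reduced_alpha_preserved(self, clean_subject):
        rec = clean_subject["rec"]
        dirty = add_mr_artifacts(
            rec, tr_s=2.0,
            amp_cfg={"gradient": 0.0, "bcg": 5.0, "eog": 0.0, "emg": 0.0},
            seed=9)
        out, _ = remove_bcg_artifact(dirty, n_obs_pcs=3)

        def locked_rms(x):
            L = int(0.8 * rec.fs)
            starts = dirty.cardiac_markers + int(-0.2 * rec.fs)
            keep = starts[(starts >= 0) & (starts + L <= rec.n_samples)]
            idx = keep[:, None] + np.arange(L)
            return np.sqrt(np.mean((x[:, idx] - rec.data[:, idx])
                                   .mean(axis=1) ** 2))

        assert 20 * np.log10(locked_rms(dirty.data) / locked_rms(out.data)) >= 10.0
        alpha_db = 10 * np.log10(band_power(out.data, rec.fs, 8, 13)
                                 / band_power(rec.data, rec.fs, 8, 13))
        assert abs(alpha_db) <= 3.0

    def test_zero_pcs_is_identity(self, contaminated_subject):
        dirty = contaminated_subject["dirty"]
        out, _ = remove_bcg_artifact(dirty, n_obs_pcs=0)
        assert np.array_equal(out.data, dirty.data)

    def test_shuffled_markers_clean_less(self, clean_subject):
        rec = clean_subject["rec"]
        dirty = add_mr_artifacts(
            rec, tr_s=2.0,
            amp_cfg={"gradient": 0.0, "bcg": 5.0, "eog": 0.0, "emg": 0.0},
            seed=9)
        rng = np.random.default_rng(0)
        fake = np.sort(rng.choice(rec.n_samples - 200, len(dirty.cardiac_markers),
                                  replace=False)) + 100
        shuffled = dirty.with_data(dirty.data)
        shuffled.cardiac_markers = np.unique(fake)
        good, _ = remove_bcg_artifact(dirty, n_obs_pcs=3)
        bad, _ = remove_bcg_artifact(shuffled, n_obs_pcs=3)
        res_good = np.sqrt(np.mean((good.data - rec.data) ** 2))
        res_bad = np.sqrt(np.mean((bad.data - rec.data) ** 2))
        assert res_good < res_bad

    def test_too_few_epochs_rejected(self):
        rec = _recording(np.random.default_rng(0).standard_normal((8, 4000)))
        rec.cardiac_markers = np.array([500, 1200])
        with pytest.raises(ValueError):
            remove_bcg_artifact(rec)


class TestRPeaks:
    def _ecg(self, bpm, dur, fs=250.0, seed=0):
        t = np.arange(int(dur * fs)) / fs
        beats = np.arange(0.3, dur - 0.3, 60.0 / bpm)
        x = 0.02 * np.random.default_rng(seed).standard_normal(len(t))
        for b in beats:
            x += np.exp(-((t - b) / 0.012) ** 2)
        return x, len(beats)

    def test_sixty_bpm_counts(self):
        x, n = self._ecg(60, 60.0)
        peaks = detect_r_peaks(x, 250.0)
        assert abs(len(peaks) - n) <= 1

    def test_flat_trace_gives_no_peaks(self):
        assert detect_r_peaks(np.zeros(5000), 250.0).size == 0

    def test_ninety_bpm_interval(self):
        x, _ = self._ecg(90, 60.0)
        peaks = detect_r_peaks(x, 250.0)
        med = np.median(np.diff(peaks)) / 250.0
        assert abs(med - 0.667) <= 0.02


class TestBadChannels:
    def _base(self, rng, n_ch=12, n=8000, fs=200.0):
        shared = rng.standard_normal(n)
        data = np.array([shared + 0.3 * rng.standard_normal(n)
                         for _ in range(n_ch)])
        return data, fs

    def test_broadband_noise_channel_flagged_alone(self, rng):
        data, fs = self._base(rng)
        data[5] = 100.0 * rng.standard_normal(data.shape[1])
        flags, report = detect_bad_channels(_recording(data, fs))
        assert flags[5]
        assert flags.sum() == 1

    def test_identical_channels_none_flagged(self):
        data = np.tile(np.sin(np.arange(8000) / 7.0), (10, 1))
        flags, _ = detect_bad_channels(_recording(data))
        assert flags.sum() == 0

    def test_flags_invariant_to_channel_order(self, rng):
        data, fs = self._base(rng)
        data[3] = 50.0 * rng.standard_normal(data.shape[1])
        rec = _recording(data, fs)
        flags, _ = detect_bad_channels(rec)
        perm = rng.permutation(data.shape[0])
        rec_p = _recording(data[perm], fs, positions=rec.positions[perm])
        flags_p, _ = detect_bad_channels(rec_p)
        assert np.array_equal(flags_p, flags[perm])

    def test_low_rate_falls_back_with_warning(self, rng):
        data, _ = self._base(rng)
        with pytest.warns(UserWarning, match="Nyquist"):
            detect_bad_channels(_recording(data, fs=200.0))


class TestInterpolation:
    def test_centroid_channel_reconstructed_exactly(self, rng):
        sig = rng.standard_normal(2000)
        pos = np.array([[10, 0, 40], [-10, 0, 40], [0, 10, 40], [0, -10, 40],
                        [0, 0, 40], [30, 30, 10], [-30, 30, 10], [30, -30, 10]],
                       dtype=float)
        data = np.vstack([sig] * 5 + [rng.standard_normal((3, 2000))])
        rec = _recording(data, positions=pos)
        flags = np.zeros(8, dtype=bool)
        flags[4] = True
        out = interpolate_channels(rec, flags)
        assert np.allclose(out.data[4], sig)

    def test_no_flags_identity(self, rng):
        rec = _recording(rng.standard_normal((8, 1000)))
        out = interpolate_channels(rec, np.zeros(8, dtype=bool))
        assert np.array_equal(out.data, rec.data)

    def test_interpolated_variance_bounded_by_neighbors(self, rng):
        rec = _recording(rng.standard_normal((12, 4000)))
        flags = np.zeros(12, dtype=bool)
        flags[0] = True
        out = interpolate_channels(rec, flags)
        assert out.data[0].var() <= rec.data[1:].var(axis=1).max()

    def test_too_many_bad_rejected(self, rng):
        rec = _recording(rng.standard_normal((8, 1000)))
        flags = np.zeros(8, dtype=bool)
        flags[:2] = True
        with pytest.raises(ValueError, match="too many"):
            interpolate_channels(rec, flags)


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs = 250.0
        t = np.arange(10000) / fs
        rec = _recording(np.tile(np.sin(2 * np.pi * 10 * t), (8, 1)), fs)
        out = bandpass_filter(rec, 1, 80)
        mid = slice(2000, 8000)
        gain = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(gain - 1.0) < 0.01

    def test_slow_drift_attenuated(self):
        fs = 250.0
        t = np.arange(50000) / fs
        rec = _recording(np.tile(np.sin(2 * np.pi * 0.1 * t), (8, 1)), fs)
        out = bandpass_filter(rec, 1, 80)
        assert 20 * np.log10(rec.data[0].std() / out.data[0].std()) >= 20.0

    def test_dc_offset_removed(self, rng):
        rec = _recording(np.full((8, 5000), 50.0) + 0.0 * rng.standard_normal((8, 5000)))
        out = bandpass_filter(rec, 1, 80)
        assert np.mean(np.abs(out.data)) < 1e-3 * 50.0

    def test_roughly_idempotent_in_passband(self, rng):
        rec = _recording(rng.standard_normal((8, 10000)))
        once = bandpass_filter(rec, 1, 80)
        twice = bandpass_filter(once, 1, 80)
        mid = slice(1000, 9000)
        rel = (np.linalg.norm(twice.data[:, mid] - once.data[:, mid])
               / np.linalg.norm(once.data[:, mid]))
        assert rel < 0.15


class TestIcClassification:
    def _decomp(self, sources):
        k, n = sources.shape
        return type("D", (), {
            "k": k, "sources": sources,
            "mixing": np.eye(k), "whitening": np.eye(k),
            "mean": np.zeros(k), "convergence": [1] * k, "seed": 0})()

    def test_ic_equal_to_eog_reference_flagged(self, rng):
        fs = 200.0
        eog = np.cumsum(rng.standard_normal(8000))
        eog /= eog.std()
        others = rng.standard_normal((2, 8000))
        sources = np.vstack([eog, others])
        ids, scores, _ = classify_artifact_ics(
            self._decomp(sources), eog, rng.standard_normal(8000), fs)
        assert 0 in ids
        assert scores["eog_corr"][0] > 0.999

    def test_clean_one_over_f_ic_not_flagged(self, rng):
        fs = 200.0
        n = 20000
        freqs = np.fft.rfftfreq(n, 1 / fs)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** -0.5
        x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * gain, n)
        x /= x.std()
        sources = np.vstack([x, rng.standard_normal((1, n))])
        ids, scores, _ = classify_artifact_ics(
            self._decomp(sources), rng.standard_normal(n),
            rng.standard_normal(n), fs)
        assert 0 not in ids
        assert scores["spec_1f_sim"][0] > 0.9

    def test_spike_train_flagged_by_kurtosis(self, rng):
        n = 8000
        spikes = np.zeros(n)
        spikes[rng.choice(n, 20, replace=False)] = 30.0
        sources = np.vstack([spikes + 0.1 * rng.standard_normal(n),
                             rng.standard_normal((1, n))])
        ids, scores, _ = classify_artifact_ics(
            self._decomp(sources), rng.standard_normal(n),
            rng.standard_normal(n), 200.0)
        assert 0 in ids
        assert scores["kurtosis"][0] > 10.0


class TestRemoveAndRereference:
    def test_empty_removal_equals_average_reference(self, rng):
        data = rng.laplace(size=(8, 5000))
        data -= data.mean(axis=1, keepdims=True)
        rec = _recording(data)
        dec = fastica_deflation(data, 8, seed=0)
        out = remove_ics_and_rereference(rec, dec, [])
        expected = data - data.mean(axis=0, keepdims=True)
        assert np.max(np.abs(out.data - expected)) < 1e-9

    def test_all_removed_gives_zero(self, rng):
        data = rng.laplace(size=(6, 5000))
        data -= data.mean(axis=1, keepdims=True)
        rec = _recording(data)
        dec = fastica_deflation(data, 6, seed=0)
        out = remove_ics_and_rereference(rec, dec, list(range(6)))
        assert np.max(np.abs(out.data)) < 1e-6 * np.abs(data).max()

    def test_output_channel_mean_zero(self, rng):
        data = rng.standard_normal((8, 4000))
        rec = _recording(data)
        dec = fastica_deflation(data, 5, seed=0)
        out = remove_ics_and_rereference(rec, dec, [0, 1])
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-9


class TestCascadeContracts:
    def test_no_operator_alters_rates_channels_or_markers(self, contaminated_subject):
        dirty = contaminated_subject["dirty"]
        s1, _ = remove_gradient_artifact(dirty, n_avg_epochs=10, n_obs_pcs=3)
        s2, _ = remove_bcg_artifact(s1, n_obs_pcs=3)
        flags, _ = detect_bad_channels(s2)
        s3 = interpolate_channels(s2, flags)
        s4 = bandpass_filter(s3, 1, 80)
        for step in (s1, s2, s3, s4):
            assert step.fs == dirty.fs
            assert step.n_channels == dirty.n_channels
            assert np.array_equal(step.tr_markers, dirty.tr_markers)
            assert np.array_equal(step.cardiac_markers, dirty.cardiac_markers)
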