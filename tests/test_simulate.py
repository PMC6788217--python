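"""Synthetic EEG + BOLD generator."""

import numpy as np
import pytest

from eegfmri.containers import GroundTruth
from eegfmri.hemo import canonical_hrf, hrf_convolve
from eegfmri.simulate import (
    add_mr_artifacts,
    make_head_model,
    make_network_maps,
    project_to_sensors,
    simulate_bold,
    simulate_sources,
)


class TestHeadModel:
    def test_leadfield_columns_average_referenced(self, small_head):
        _, lf = small_head
        sums = lf.matrix.sum(axis=0)
        norms = np.linalg.norm(lf.matrix, axis=0)
        assert np.max(np.abs(sums)) < 1e-9 * norms.max()

    def test_deterministic_given_seed(self):
        g1, l1 = make_head_model(32, (6, 6, 6), 6.0, seed=1)
        g2, l2 = make_head_model(32, (6, 6, 6), 6.0, seed=1)
        assert np.array_equal(l1.matrix, l2.matrix)
        assert np.array_equal(g1.coords, g2.coords)

    def test_mirror_symmetric_sensors_see_antisymmetric_potentials(self):
        # a dipole at the origin with a moment in +x: potentials at sensor
        # positions mirrored through the x=0 plane cancel pairwise
        from eegfmri.simulate import _dipole_potentials
        sensors = np.array([[40.0, 10.0, 30.0], [-40.0, 10.0, 30.0],
                            [25.0, -15.0, 42.0], [-25.0, -15.0, 42.0]])
        lf = _dipole_potentials(sensors, np.zeros((1, 3)))
        v = lf[:, 0]                      # unit moment along x
        assert abs(v[0] + v[1]) < 1e-9 * np.abs(v).max()
        assert abs(v[2] + v[3]) < 1e-9 * np.abs(v).max()

    def test_too_few_sensors_rejected(self):
        with pytest.raises(ValueError):
            make_head_model(4, (4, 4, 3))
        with pytest.raises(ValueError):
            make_head_model(16, (2, 2, 2))


class TestSimulateSources:
    def test_alpha_carrier_spectral_concentration(self, small_head):
        grid, _ = small_head
        src, truth = simulate_sources(grid, 1, ("alpha",), duration_s=60,
                                      fs=200, background_amp=0.0, seed=2)
        v = int(np.argmax(truth.network_maps[:, 0]))
        x = src.activity[v]
        freqs = np.fft.rfftfreq(len(x), 1 / 200.0)
        p = np.abs(np.fft.rfft(x)) ** 2
        in_band = p[(freqs >= 8) & (freqs <= 13)].sum()
        assert in_band / p.sum() > 0.95

    def test_zero_network_amp_leaves_background_only(self, small_head):
        grid, _ = small_head
        src, _ = simulate_sources(grid, 1, ("alpha",), duration_s=60, fs=200,
                                  network_amp=0.0, background_amp=0.0, seed=2)
        assert np.allclose(src.activity, 0.0)

    def test_deterministic_given_seed(self, small_head):
        grid, _ = small_head
        _, t1 = simulate_sources(grid, 1, ("alpha",), 60, 200, seed=3)
        _, t2 = simulate_sources(grid, 1, ("alpha",), 60, 200, seed=3)
        assert np.array_equal(t1.network_maps, t2.network_maps)
        assert np.array_equal(t1.envelopes, t2.envelopes)

    def test_band_outside_range_rejected(self, small_head):
        grid, _ = small_head
        with pytest.raises(ValueError):
            simulate_sources(grid, 1, ((0.5, 4.0),), 60, 200, seed=1)
        with pytest.raises(ValueError):
            simulate_sources(grid, 1, ("alpha",), 30, 200, seed=1)

    def test_maps_live_in_gray_matter(self, small_head):
        grid, _ = small_head
        maps = make_network_maps(grid, K=2, seed=9)
        assert np.all(maps[~grid.gm_mask] == 0)
        assert np.all((maps != 0).sum(axis=0) >= 1)


class TestProjection:
    def test_zero_sources_zero_recording(self, small_head):
        grid, lf = small_head
        src, _ = simulate_sources(grid, 1, ("alpha",), 60, 200,
                                  network_amp=0.0, background_amp=0.0, seed=2)
        rec = project_to_sensors(lf, src)
        assert np.allclose(rec.data, 0.0)

    def test_superposition(self, small_head, rng):
        grid, lf = small_head
        V = grid.n_voxels
        a = rng.standard_normal((V, 3, 50))
        b = rng.standard_normal((V, 3, 50))
        ra = project_to_sensors(lf, a, fs=200.0).data
        rb = project_to_sensors(lf, b, fs=200.0).data
        rab = project_to_sensors(lf, a + 2 * b, fs=200.0).data
        assert np.max(np.abs(rab - (ra + 2 * rb))) < 1e-9 * np.abs(rab).max()

    def test_doubling_one_voxel_doubles_its_contribution(self, small_head, rng):
        grid, lf = small_head
        V = grid.n_voxels
        src = np.zeros((V, 3, 20))
        src[5] = rng.standard_normal((3, 20))
        r1 = project_to_sensors(lf, src, fs=200.0).data
        r2 = project_to_sensors(lf, 2 * src, fs=200.0).data
        assert np.allclose(r2, 2 * r1)


class TestArtifacts:
    def test_gradient_raises_variance_a_thousandfold(self, clean_subject):
        rec = clean_subject["rec"]
        dirty = add_mr_artifacts(
            rec, tr_s=2.0,
            amp_cfg={"gradient": 50.0, "bcg": 0.0, "eog": 0.0, "emg": 0.0},
            seed=1)
        assert dirty.data.var() / rec.data.var() >= 1000.0

    def test_zero_amplitudes_identity(self, clean_subject):
        rec = clean_subject["rec"]
        out = add_mr_artifacts(
            rec, tr_s=2.0,
            amp_cfg={"gradient": 0.0, "bcg": 0.0, "eog": 0.0, "emg": 0.0},
            seed=1)
        assert np.array_equal(out.data, rec.data)
        assert out.tr_markers.size > 0          # markers are still recorded

    def test_cardiac_marker_spacing_matches_heart_rate(self, clean_subject):
        rec = clean_subject["rec"]
        out = add_mr_artifacts(rec, tr_s=2.0, cardiac_bpm=75.0, jitter_ms=40.0,
                               seed=2)
        spacing = np.diff(out.cardiac_markers) / rec.fs
        assert abs(np.median(spacing) - 60.0 / 75.0) < 0.05

    def test_negative_amplitude_rejected(self, clean_subject):
        with pytest.raises(ValueError):
            add_mr_artifacts(clean_subject["rec"], tr_s=2.0,
                             amp_cfg={"gradient": -1.0}, seed=1)

    def test_gradient_exactly_epoch_periodic(self, clean_subject):
        rec = clean_subject["rec"]
        zeros = rec.with_data(np.zeros_like(rec.data))
        dirty = add_mr_artifacts(
            zeros, tr_s=2.0,
            amp_cfg={"gradient": 50.0, "bcg": 0.0, "eog": 0.0, "emg": 0.0},
            seed=3)
        L = int(2.0 * rec.fs)
        epochs = np.stack([dirty.data[:, m:m + L] for m in dirty.tr_markers
                           if m + L <= rec.n_samples])
        assert np.max(np.abs(epochs - epochs[0])) == 0.0


class TestBold:
    def _truth(self, grid, onset=None):
        maps = make_network_maps(grid, 1, seed=4)
        T = 120
        env = np.ones((1, T))
        if onset is not None:
            env = np.zeros((1, T))
            env[0, onset:onset + 2] = 1.0
        return GroundTruth(network_maps=maps, envelopes=env,
                           carrier_bands=["alpha"])

    def test_zero_envelope_zero_noise_gives_zero_series(self, small_head):
        grid, _ = small_head
        truth = self._truth(grid)
        truth.envelopes[:] = 0.0
        vol = simulate_bold(truth, grid, tr_s=2.0, noise_sd=0.0, drift_amp=0.0,
                            seed=0)
        assert np.allclose(vol.values, 0.0)

    def test_boxcar_response_peaks_at_hemodynamic_lag(self, small_head):
        grid, _ = small_head
        truth = self._truth(grid, onset=20)
        vol = simulate_bold(truth, grid, tr_s=1.0, noise_sd=0.0, drift_amp=0.0,
                            seed=0)
        v = int(np.argmax(truth.network_maps[:, 0]))
        peak_t = float(np.argmax(vol.values[v]))   # tr = 1 s
        assert 24.0 <= peak_t <= 27.0
        # fine-grid oracle: HRF ⊗ boxcar evaluated directly
        kern = canonical_hrf(0.05)
        t = np.arange(0, 120, 0.05)
        box = ((t >= 20) & (t < 22)).astype(float)
        oracle_peak = t[np.argmax(np.convolve(box, kern.samples)[: len(t)])]
        assert abs(peak_t - oracle_peak) <= 1.5

    def test_out_of_network_voxel_is_drift_only(self, small_head):
        grid, _ = small_head
        truth = self._truth(grid)
        vol = simulate_bold(truth, grid, tr_s=2.0, noise_sd=0.0, drift_amp=0.5,
                            seed=7)
        drift_only = simulate_bold(
            GroundTruth(network_maps=np.where(truth.network_maps > -1, 0, 0)
                        + 1e-300 * (truth.network_maps == truth.network_maps),
                        envelopes=truth.envelopes,
                        carrier_bands=truth.carrier_bands),
            grid, tr_s=2.0, noise_sd=0.0, drift_amp=0.5, seed=7)
        out_vox = np.nonzero(truth.network_maps[:, 0] == 0)[0]
        assert np.allclose(vol.values[out_vox], drift_only.values[out_vox])

    def test_coupling_consistency_noiseless(self, small_head):
        grid, _ = small_head
        maps = make_network_maps(grid, 1, seed=4)
        rng = np.random.default_rng(0)
        env = np.abs(rng.standard_normal(120)).cumsum() * 0.01 + \
            np.abs(rng.standard_normal(120))
        truth = GroundTruth(network_maps=maps, envelopes=env[None, :],
                            carrier_bands=["alpha"])
        vol = simulate_bold(truth, grid, tr_s=2.0, noise_sd=0.0, drift_amp=0.0,
                            seed=0)
        kern = canonical_hrf(1.0)
        reg = hrf_convolve(env, kern)[::2][: vol.n_volumes]
        for v in np.nonzero(maps[:, 0] > 0)[0][:5]:
            r = np.corrcoef(reg, vol.values[v])[0, 1]
            assert r > 1 - 1e-9

    def test_too_many_volumes_rejected(self, small_head):
        grid, _ = small_head
        truth = self._truth(grid)
        with pytest.raises(ValueError):
            simulate_bold(truth, grid, tr_s=2.0, n_volumes=100, seed=0)
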