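"""Synthetic generator: source spectra, lag fields, reconstruction identity."""

import numpy as np
import pytest
from scipy.signal import periodogram

from lagwave import (SimulationConfig, WaveSpec, build_lag_field,
                     generate_band_limited_source, simulate_dataset, sinc_shift)


class TestBandLimitedSource:
    def test_deterministic_given_seed(self):
        a = generate_band_limited_source(600, 0.72, (0.01, 0.1), seed=7)
        b = generate_band_limited_source(600, 0.72, (0.01, 0.1), seed=7)
        assert np.array_equal(a, b)

    def test_standardized(self):
        s = generate_band_limited_source(1200, 0.72, (0.01, 0.1), seed=1)
        assert abs(s.mean()) < 1e-9
        assert abs(s.var() - 1.0) < 1e-9

    def test_power_concentrated_in_band(self):
        s = generate_band_limited_source(1200, 0.72, (0.01, 0.1), seed=2)
        f, p = periodogram(s, fs=1 / 0.72)
        in_band = p[(f >= 0.0095) & (f <= 0.1005)].sum()
        assert in_band / p.sum() >= 0.95

    def test_super_gaussian(self):
        from scipy.stats import kurtosis
        ks = [kurtosis(generate_band_limited_source(1200, 0.72, seed=s))
              for s in range(10)]
        assert np.mean(ks) > 0.5

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_band_limited_source(600, 0.72, (0.01, 0.8), seed=0)


class TestLagField:
    def test_origin_has_zero_lag(self):
        idx = np.array([[2, 2, 2], [5, 2, 2]])
        lags = build_lag_field(idx, (2, 2, 2), speed=2.0)
        assert lags[0] == 0.0

    def test_isotropy_equidistant_voxels(self):
        idx = np.array([[5, 2, 2], [2, 5, 2], [2, 2, 5]])
        lags = build_lag_field(idx, (2, 2, 2), speed=1.7)
        assert np.allclose(lags, lags[0])

    def test_distance_over_speed(self):
        idx = np.array([[3, 0, 0]])
        lags = build_lag_field(idx, (0, 0, 0), speed=1.5, pitch=1.0)
        assert lags[0] == pytest.approx(2.0)

    def test_window_overflow_warns(self):
        idx = np.array([[0, 0, 0], [30, 0, 0]])
        with pytest.warns(UserWarning, match="exceeds the analysis window"):
            build_lag_field(idx, (0, 0, 0), speed=1.0, max_lag=6.3)


class TestSimulateDataset:
    def test_noiseless_voxel_matches_shifted_source(self, small_sim):
        ds, truth, _, _ = small_sim
        v = 17
        a, b = ds.run_bounds[0]
        expected = truth.magnitude_fields[0][v] * sinc_shift(
            truth.sources[0][a:b], truth.lag_fields[0][v] / ds.tr)
        seg = ds.data[v, a:b]
        r = np.corrcoef(seg[30:-30], expected[30:-30])[0, 1]
        assert r > 1 - 1e-6

    def test_reconstruction_identity_interior(self, small_sim):
        ds, truth, _, _ = small_sim
        rebuilt = np.zeros_like(ds.data)
        for r, (a, b) in enumerate(ds.run_bounds):
            seg = truth.sources[0][a:b]
            for v in range(ds.n_voxels):
                rebuilt[v, a:b] = truth.magnitude_fields[0][v] * sinc_shift(
                    seg, truth.lag_fields[0][v] / ds.tr)
        T_run = ds.run_bounds[0][1]
        lo, hi = int(0.05 * T_run), int(0.95 * T_run)
        for a, b in ds.run_bounds:
            err = np.abs(rebuilt[:, a + lo:a + hi] - ds.data[:, a + lo:a + hi]).max()
            assert err < 1e-8

    def test_same_network_voxels_synchronized(self):
        cfg = SimulationConfig(shape=(12, 12, 4), timepoints_per_run=600, n_runs=2,
                               n_global=0, n_local=2, noise_sd=0.0, seed=9)
        ds, truth, _, _ = simulate_dataset(cfg)
        net = np.flatnonzero(truth.network_masks[0])
        r_same = np.corrcoef(ds.data[net[0]], ds.data[net[1]])[0, 1]
        assert r_same == pytest.approx(1.0, abs=1e-9)
        other = np.flatnonzero(truth.network_masks[1] & ~truth.network_masks[0])
        r_cross = np.corrcoef(ds.data[net[0]], ds.data[other[0]])[0, 1]
        assert abs(r_cross) < 0.2

    def test_variance_additivity_with_noise(self):
        # voxel variance = signal variance + noise_sd^2 for uncorrelated terms
        ratios = []
        for seed in range(30):
            cfg = SimulationConfig(shape=(8, 8, 3), timepoints_per_run=300,
                                   n_runs=1, n_global=1, n_local=0,
                                   magnitude_fields=None, noise_sd=0.5, seed=seed)
            ds, truth, _, _ = simulate_dataset(cfg)
            v = 10
            mag2 = truth.magnitude_fields[0][v] ** 2
            ratios.append(ds.data[v].var() / (mag2 + 0.25))
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_seed_determinism(self):
        cfg = SimulationConfig(shape=(8, 8, 3), timepoints_per_run=300, n_runs=1,
                               n_global=1, n_local=1, noise_sd=0.3, seed=42)
        d1 = simulate_dataset(cfg)[0]
        d2 = simulate_dataset(cfg)[0]
        assert np.array_equal(d1.data, d2.data)

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_global=0, n_local=0)

    def test_template_set_structure(self, small_noisy_sim):
        _, truth, templates, _ = small_noisy_sim
        assert templates.whole_brain in templates.templates
        assert len(templates.network_names) == 2

    def test_roi_partition_covers_mask(self, small_noisy_sim):
        ds, truth, _, rois = small_noisy_sim
        assert (rois.labels > 0).all()
        for l, m in enumerate(truth.network_masks):
            labs = np.unique(rois.labels[m])
            assert labs.size >= 1
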