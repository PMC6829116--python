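"""ROI connectivity matrices, comparisons, partial correlation, smoothness."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from lagwave import (compare_matrices, correlation_matrix, estimate_resels,
                     lag_matrix, matrix_upper_correlation,
                     partial_correlation_maps, roi_mean_timeseries)
from lagwave.lagmap import LagMap
from lagwave.types import ROISet

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class TestRoiMeans:
    def test_single_voxel_roi_is_its_series(self, rng):
        sig = rng.standard_normal((3, 50))
        rois = ROISet(labels=np.array([1, 2, 2]))
        series, labels = roi_mean_timeseries(sig, rois)
        assert np.array_equal(series[0], sig[0])

    def test_opposite_series_cancel(self, rng):
        s = rng.standard_normal(50)
        series, _ = roi_mean_timeseries(np.vstack([s, -s]), ROISet(labels=np.array([1, 1])))
        assert np.abs(series[0]).max() < 1e-12


class TestCorrelationMatrix:
    def test_duplicated_roi_gives_unit_offdiagonal(self, rng):
        s = rng.standard_normal(100)
        fc = correlation_matrix(np.vstack([s, s]))
        assert fc.r[0, 1] == pytest.approx(1.0)

    def test_independent_rois_nearly_uncorrelated(self):
        offs = []
        for seed in range(10):
            series = np.random.default_rng(seed).standard_normal((8, 1200))
            fc = correlation_matrix(series)
            offs.append(np.abs(fc.r[np.triu_indices(8, 1)]).mean())
        assert np.mean(offs) < 0.06

    def test_positive_semidefinite(self, rng):
        fc = correlation_matrix(rng.standard_normal((6, 100)))
        assert np.linalg.eigvalsh(fc.r).min() > -1e-10

    def test_constant_roi_warns_nan(self, rng):
        series = np.vstack([np.ones(50), rng.standard_normal(50)])
        with pytest.warns(UserWarning, match="constant"):
            fc = correlation_matrix(series)
        assert np.isnan(fc.r[0, 1])


class TestLagMatrix:
    def test_pairwise_absolute_differences(self):
        lm = LagMap(lag=np.array([0.0, 2.0, 5.0]), valid=np.ones(3, bool), window=6.3)
        rois = ROISet(labels=np.array([1, 2, 3]))
        d = lag_matrix(lm, rois).d
        assert np.allclose(d, [[0, 2, 5], [2, 0, 3], [5, 3, 0]])

    def test_uniform_lags_give_zeros(self):
        lm = LagMap(lag=np.full(4, 1.3), valid=np.ones(4, bool), window=6.3)
        d = lag_matrix(lm, ROISet(labels=np.array([1, 1, 2, 2]))).d
        assert np.abs(d).max() == 0.0

    def test_mostly_invalid_roi_dropped(self):
        lm = LagMap(lag=np.array([0.0, np.nan, np.nan, 1.0]),
                    valid=np.array([True, False, False, True]), window=6.3)
        rois = ROISet(labels=np.array([1, 1, 1, 2]))
        with pytest.warns(UserWarning, match="dropped"):
            out = lag_matrix(lm, rois)
        assert out.roi_labels == [2]

    def test_all_rois_dropped_raises(self):
        lm = LagMap(lag=np.full(2, np.nan), valid=np.zeros(2, bool), window=6.3)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="all ROIs"):
                lag_matrix(lm, ROISet(labels=np.array([1, 2])))


class TestCompareMatrices:
    def test_identical_matrices_give_unit_r(self, rng):
        m = np.corrcoef(rng.standard_normal((5, 60)))
        cmp = compare_matrices([m, m], [m, m])
        assert np.allclose(cmp.r_per_run, 1.0)

    def test_negated_offdiagonal_gives_minus_one(self, rng):
        m = np.corrcoef(rng.standard_normal((5, 60)))
        m2 = -m.copy()
        np.fill_diagonal(m2, 1.0)
        assert matrix_upper_correlation(m, m2) == pytest.approx(-1.0)

    def test_zero_association_gives_t0_p1(self, rng):
        # matrices whose upper-triangle correlation is exactly 0 in each run
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        a[0, 2] = a[2, 0] = -1.0
        b = np.zeros((3, 3))
        b[0, 1] = b[1, 0] = 1.0
        b[0, 2] = b[2, 0] = 1.0
        b[1, 2] = b[2, 1] = -2.0
        cmp = compare_matrices([a] * 4, [b] * 4)
        assert cmp.t == 0.0 and cmp.p == pytest.approx(1.0)

    def test_run_order_invariance(self, rng):
        ms1 = [np.corrcoef(rng.standard_normal((5, 60))) for _ in range(4)]
        ms2 = [np.corrcoef(rng.standard_normal((5, 60))) for _ in range(4)]
        c1 = compare_matrices(ms1, ms2)
        c2 = compare_matrices(ms1[::-1], ms2[::-1])
        assert c1.p == pytest.approx(c2.p)

    def test_bonferroni_multiplies(self, rng):
        ms1 = [np.corrcoef(rng.standard_normal((5, 60))) for _ in range(4)]
        ms2 = [np.corrcoef(rng.standard_normal((5, 60))) for _ in range(4)]
        c1 = compare_matrices(ms1, ms2, n_comparisons=1)
        c4 = compare_matrices(ms1, ms2, n_comparisons=4)
        assert c4.p_bonferroni == pytest.approx(min(1.0, 4 * c1.p))


class TestPartialCorrelation:
    def test_uncorrelated_control_leaves_r(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        z = rng.standard_normal(n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_p = partial_correlation_maps(x, y, z, np.ones(n, bool))
        assert abs(r_p - r_xy) < 0.05

    def test_hand_case(self):
        # r_xy = r_xz = r_yz = 0.5 -> (0.5 - 0.25) / 0.75 = 1/3
        r = (0.5 - 0.5 * 0.5) / np.sqrt((1 - 0.25) * (1 - 0.25))
        assert r == pytest.approx(1.0 / 3.0)

    def test_control_equal_to_input_rejected(self, rng):
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        with pytest.raises(ValueError):
            partial_correlation_maps(x, y, x, np.ones(100, bool))


class TestResels:
    def test_fwhm_recovered_from_known_smoothing(self):
        ests = []
        for seed in range(3):
            f = np.random.default_rng(seed).standard_normal((48, 48, 48))
            sm = gaussian_filter(f, 3.0 * FWHM_TO_SIGMA)
            est = estimate_resels(sm, np.ones((48, 48, 48), bool))
            ests.append(est.fwhm.mean())
        assert abs(np.mean(ests) - 3.0) / 3.0 < 0.1

    def test_resels_scale_with_smoothing(self):
        f = np.random.default_rng(0).standard_normal((48, 48, 48))
        mask = np.ones((48, 48, 48), bool)
        r2 = estimate_resels(gaussian_filter(f, 2.0 * FWHM_TO_SIGMA), mask).resels
        r4 = estimate_resels(gaussian_filter(f, 4.0 * FWHM_TO_SIGMA), mask).resels
        assert abs(r4 / (r2 / 8.0) - 1.0) < 0.15

    def test_effective_dof_decreases_with_smoothing(self):
        f = np.random.default_rng(1).standard_normal((48, 48, 48))
        mask = np.ones((48, 48, 48), bool)
        resels = [estimate_resels(gaussian_filter(f, s), mask).resels
                  for s in (1.0, 2.0, 3.0)]
        assert resels[0] > resels[1] > resels[2]

    def test_corrected_p_uses_resel_dof(self):
        f = np.random.default_rng(2).standard_normal((48, 48, 48))
        est = estimate_resels(gaussian_filter(f, 2.0), np.ones((48, 48, 48), bool))
        p_small = est.corrected_p(0.9)
        p_large = est.corrected_p(0.1)
        assert p_small < p_large

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            estimate_resels(np.ones((10, 10, 10)), np.ones((10, 10, 10), bool))
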