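"""ROI connectivity matrices, matrix comparison, and spatial-dof correction.

The headline statistic of the pipeline: how well the ROI-wise correlation
matrix of each reconstructed signal variant (global, local, lag-only)
reproduces the functional-connectivity matrix of the full signal, tested
run-wise on Fisher-Z transformed upper-triangle correlations. Also provides
the FC-vs-time-lag matrix comparison, partial correlation of spatial maps
controlling a confound map, and Gaussian-random-field smoothness (FWHM /
resel) estimation for map-correlation inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lagmap import LagMap
from .types import ROISet


@dataclass
class FCMatrix:
    r: np.ndarray            # (R, R) symmetric, unit diagonal
    roi_labels: list[int]


@dataclass
class LagMatrix:
    d: np.ndarray            # (R, R) absolute lag differences, seconds
    roi_labels: list[int]


@dataclass
class MatrixComparison:
    r_per_run: np.ndarray
    z_per_run: np.ndarray
    mean_r: float
    t: float
    p: float
    p_bonferroni: float
    n_comparisons: int


@dataclass
class SmoothnessEstimate:
    fwhm: np.ndarray         # per-axis, voxels
    resels: float
    n_voxels: int

    def corrected_p(self, r: float) -> float:
        """Two-tailed p for a map-map correlation with effective dof = resels - 2."""
        df = self.resels - 2.0
        if df <= 0:
            raise ValueError("fewer than 3 resels; correlation test undefined")
        t = r * np.sqrt(df / max(1e-12, 1.0 - r ** 2))
        return float(2.0 * stats.t.sf(abs(t), df))


def roi_mean_timeseries(signal: np.ndarray, rois: ROISet) -> tuple[np.ndarray, list[int]]:
    """Unweighted mean series per ROI; returns (R x T matrix, roi labels)."""
    signal = np.asarray(signal, float)
    out = []
    labels = rois.roi_labels
    for k in labels:
        sel = rois.labels == k
        if not sel.any():
            raise ValueError(f"ROI {rois.names[k]!r} has no voxels")
        out.append(signal[sel].mean(axis=0))
    return np.stack(out), labels


def correlation_matrix(roi_series: np.ndarray, roi_labels=None) -> FCMatrix:
    """Pearson correlation between every pair of ROI series."""
    roi_series = np.asarray(roi_series, float)
    if roi_series.shape[1] < 3:
        raise ValueError("at least 3 timepoints are required")
    sd = roi_series.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} constant ROI series; entries set NaN",
                      UserWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(roi_series)
    np.fill_diagonal(r, 1.0)
    labels = list(roi_labels) if roi_labels is not None else list(range(roi_series.shape[0]))
    return FCMatrix(r=r, roi_labels=labels)


def lag_matrix(lag_map: LagMap, rois: ROISet, min_valid_fraction: float = 0.5) -> LagMatrix:
    """Absolute difference of ROI-mean lags for every ROI pair.

    ROIs whose valid-voxel fraction is below ``min_valid_fraction`` are
    dropped with a warning.
    """
    means, labels = [], []
    for k in rois.roi_labels:
        sel = rois.labels == k
        frac = lag_map.valid[sel].mean()
        if frac < min_valid_fraction:
            warnings.warn(f"ROI {rois.names[k]!r} dropped: only {frac:.0%} valid voxels",
                          UserWarning)
            continue
        means.append(np.nanmean(lag_map.lag[sel]))
        labels.append(k)
    if not labels:
        raise ValueError("all ROIs dropped: no ROI has enough valid lag voxels")
    m = np.asarray(means)
    return LagMatrix(d=np.abs(m[:, None] - m[None, :]), roi_labels=labels)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def matrix_upper_correlation(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson r of the upper triangles (diagonal excluded), pairwise-complete."""
    x, y = _upper(np.asarray(m1, float)), _upper(np.asarray(m2, float))
    ok = np.isfinite(x) & np.isfinite(y)
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"{n_bad} non-finite matrix entries excluded pairwise", UserWarning)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 finite upper-triangle pairs")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def compare_matrices(matrices_1: list[np.ndarray], matrices_2: list[np.ndarray],
                     n_comparisons: int = 1) -> MatrixComparison:
    """Run-wise upper-triangle correlation of two matrix families.

    Per run: Pearson r over the off-diagonal upper triangle, Fisher-Z
    transformed; the group statistic is a one-sample two-tailed t-test of
    the Z values against 0, Bonferroni-corrected by the configured family
    size of planned comparisons.
    """
    if len(matrices_1) != len(matrices_2):
        raise ValueError("the two matrix families must pair up run-wise")
    rs = np.array([matrix_upper_correlation(a, b)
                   for a, b in zip(matrices_1, matrices_2)])
    zs = np.arctanh(np.clip(rs, -1 + 1e-15, 1 - 1e-15))
    if len(rs) >= 2:
        t, p = stats.ttest_1samp(zs, 0.0)
        if np.isnan(t):  # zero variance across runs
            t, p = (np.inf if zs[0] != 0 else 0.0), (0.0 if zs[0] != 0 else 1.0)
    else:
        t, p = np.nan, np.nan
    return MatrixComparison(r_per_run=rs, z_per_run=zs, mean_r=float(rs.mean()),
                            t=float(t), p=float(p),
                            p_bonferroni=float(min(1.0, p * n_comparisons)),
                            n_comparisons=n_comparisons)


def partial_correlation_maps(map_x: np.ndarray, map_y: np.ndarray, map_z: np.ndarray,
                             mask: np.ndarray) -> float:
    """Partial correlation of two spatial maps controlling a third.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) * (1 - r_yz^2))
    """
    mask = np.asarray(mask, bool)
    sel = mask & np.isfinite(map_x) & np.isfinite(map_y) & np.isfinite(map_z)
    x, y, z = (np.asarray(m, float)[sel] for m in (map_x, map_y, map_z))
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.ptp(v) == 0:
            raise ValueError(f"map {name} is constant over the mask")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("control map is perfectly correlated with an input map; "
                         "partial correlation undefined")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2)))


def estimate_resels(fields: np.ndarray, mask: np.ndarray) -> SmoothnessEstimate:
    """Per-axis FWHM and resel count of a field (or stack) on a 3-D grid.

    The field(s) are standardized over the mask; the variance of forward
    spatial differences gives the lag-one spatial autocorrelation, from which
    a Gaussian-autocorrelation FWHM is solved per axis (this removes the
    finite-difference bias of the naive derivative-variance estimator).
    resels = mask volume / product of per-axis FWHMs.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D grid")
    n_vox = int(mask.sum())
    if n_vox < 100:
        raise ValueError("mask must contain at least 100 voxels")
    fields = np.asarray(fields, float)
    if fields.ndim == 3:
        fields = fields[..., None]
    if fields.shape[:3] != mask.shape:
        raise ValueError("fields must share the mask grid")
    fwhm = np.empty(3)
    for axis in range(3):
        num = 0.0
        count = 0
        for j in range(fields.shape[3]):
            f = fields[..., j]
            vals = f[mask]
            sd = vals.std()
            if sd == 0:
                raise ValueError("constant field: smoothness undefined")
            u = (f - vals.mean()) / sd
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            both = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
            diff = (u[tuple(sl_hi)] - u[tuple(sl_lo)])[both]
            num += float((diff ** 2).sum())
            count += diff.size
        v = num / count                       # E[(u(x+1) - u(x))^2] = 2 (1 - rho1)
        rho1 = 1.0 - v / 2.0
        if rho1 > 0.05:
            s2 = -1.0 / (4.0 * np.log(rho1))  # Gaussian ACF: rho1 = exp(-1/(4 s^2))
            fwhm[axis] = np.sqrt(8.0 * np.log(2.0) * s2)
        else:                                 # near-white field: naive estimator
            fwhm[axis] = np.sqrt(4.0 * np.log(2.0) / v)
    resels = n_vox / float(np.prod(fwhm))
    resels = min(resels, float(n_vox))
    return SmoothnessEstimate(fwhm=fwhm, resels=resels, n_voxels=n_vox)
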