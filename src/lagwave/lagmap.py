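"""Voxel-wise time-lag and magnitude mapping against an IC time course.

For every voxel, the cross-correlation with the reference component is
scanned over integer lags within +/- the analysis window (9 TR by default,
i.e. 6.3 s at TR = 0.72 s), the discrete peak is restricted to positive
correlations, and the peak position is refined to sub-sample precision with
parabolic interpolation. The magnitude map is the Pearson correlation of the
voxel series with the component sinc-shifted by the voxel's refined lag.

Sign convention (package-wide): positive lag means the voxel's series is
DELAYED relative to the component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shift import sinc_shift
from .types import Dataset

DEFAULT_MAX_LAG_S = 6.3  # +/- 9 TR at TR = 0.72 s


@dataclass
class LagMap:
    lag: np.ndarray     # (V,) seconds; NaN where invalid
    valid: np.ndarray   # (V,) bool
    window: float       # max |lag| scanned, seconds


@dataclass
class MagnitudeMap:
    r: np.ndarray       # (V,) Pearson r at the refined lag; NaN where invalid
    r_full: np.ndarray | None = None
    """Complete non-negative magnitude map for template matching: equals ``r``
    where the refined peak is valid, the discrete best positive correlation at
    voxels whose peak sits on the window edge, and 0 where no positive
    correlation exists. Every voxel carries a value, so spatially confined
    components keep their low-magnitude contrast outside their territory."""


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else np.nan


def lagged_correlation(series_a: np.ndarray, series_b: np.ndarray,
                       max_lag_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of two series at every integer lag in [-max, +max].

    Correlation at lag k uses the overlapping samples only (no zero padding,
    no wraparound). Positive k means ``series_a`` is delayed relative to
    ``series_b``.

    Returns (lags, correlations).
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = a.size
    if n <= 2 * max_lag_samples:
        raise ValueError("series length must exceed twice the maximum lag")
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    rs = np.empty(lags.size)
    for i, k in enumerate(lags):
        if n - abs(k) < 10:
            raise ValueError(f"overlap at lag {k} is shorter than 10 samples")
        if k >= 0:
            rs[i] = _pearson(a[k:], b[: n - k])
        else:
            rs[i] = _pearson(a[: n + k], b[-k:])
    return lags, rs


def _lagged_correlation_matrix(data: np.ndarray, ref: np.ndarray,
                               max_lag_samples: int) -> np.ndarray:
    """Vectorized overlap-based lagged correlation of many voxels vs one ref.

    Returns (V, 2*max_lag+1); column i corresponds to lag i - max_lag.
    """
    V, n = data.shape
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    out = np.empty((V, lags.size))
    for i, k in enumerate(lags):
        if k >= 0:
            seg_a, seg_b = data[:, k:], ref[: n - k]
        else:
            seg_a, seg_b = data[:, : n + k], ref[-k:]
        a = seg_a - seg_a.mean(axis=1, keepdims=True)
        b = seg_b - seg_b.mean()
        denom = np.sqrt((a * a).sum(axis=1) * (b @ b))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, i] = (a @ b) / denom
    return out


def parabolic_peak(c_minus: float, c_0: float, c_plus: float) -> float:
    """Sub-sample offset of a peak from three correlation samples.

    Fits the parabola through (-1, c_minus), (0, c_0), (+1, c_plus) and
    returns the vertex abscissa in (-1, 1). ``c_0`` must be the discrete
    extremum. A flat triple (zero curvature) returns 0.
    """
    if c_0 < max(c_minus, c_plus):
        raise ValueError("c_0 must be the discrete extremum of the triple")
    denom = c_minus - 2.0 * c_0 + c_plus
    if denom == 0:
        return 0.0
    return 0.5 * (c_minus - c_plus) / denom


def map_component(dataset: Dataset, ic_series: np.ndarray,
                  max_lag: float = DEFAULT_MAX_LAG_S) -> tuple[LagMap, MagnitudeMap]:
    """Per-voxel lag (seconds) and magnitude of one component over a dataset.

    The scan and refinement run per run; the per-run lag and magnitude maps
    are then averaged over the runs in which the voxel had a valid peak. A
    voxel is invalid in a run when its best correlation is non-positive or
    its discrete peak sits on the window edge (parabolic refinement needs
    both neighbors); it is invalid overall when invalid in every run.
    """
    ic_series = np.asarray(ic_series, float)
    if ic_series.size != dataset.n_timepoints:
        raise ValueError("component series must align with the dataset timepoints")
    tr = dataset.tr
    M = int(round(max_lag / tr))
    V = dataset.n_voxels
    lag_runs = np.full((dataset.n_runs, V), np.nan)
    mag_runs = np.full((dataset.n_runs, V), np.nan)
    full_runs = np.zeros((dataset.n_runs, V))
    for ri, (a, b) in enumerate(dataset.run_bounds):
        seg = dataset.data[:, a:b]
        ref = ic_series[a:b]
        R = _lagged_correlation_matrix(seg, ref, M)
        R = np.where(np.isfinite(R), R, -np.inf)  # constant voxels -> no peak
        k_star = np.argmax(R, axis=1)
        peak_r = R[np.arange(V), k_star]
        full_runs[ri] = np.maximum(peak_r, 0.0)
        ok = (peak_r > 0) & (k_star > 0) & (k_star < 2 * M)
        for v in np.flatnonzero(ok):
            k = k_star[v]
            offset = parabolic_peak(R[v, k - 1], R[v, k], R[v, k + 1])
            t_prime = (k - M + offset) * tr
            lag_runs[ri, v] = t_prime
            shifted = sinc_shift(ref, t_prime / tr)
            mag_runs[ri, v] = _pearson(seg[v], shifted)
    valid = np.any(np.isfinite(lag_runs), axis=0)
    if not valid.any():
        raise ValueError("no voxel produced a valid positive-correlation peak")
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        lag = np.nanmean(lag_runs, axis=0)
        mag = np.nanmean(mag_runs, axis=0)
    lag[~valid] = np.nan
    mag[~valid] = np.nan
    r_full = full_runs.mean(axis=0)
    r_full[valid] = mag[valid]
    return LagMap(lag=lag, valid=valid, window=M * tr), MagnitudeMap(r=mag, r_full=r_full)


def dense_lag_search(series_a: np.ndarray, series_b: np.ndarray,
                     max_lag_samples: float, step: float = 0.01) -> float:
    """Brute-force sub-sample lag: maximize Pearson r of ``series_a`` against
    ``series_b`` sinc-shifted over a dense lag grid.

    A slow reference implementation, independent of the scan + parabolic
    path, used for validation.
    """
    from .shift import DEFAULT_RADIUS
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    # correlate over interior samples only: the shifted copy is zero-padded at
    # the edges, which would otherwise bias the dense objective relative to
    # the overlap-based scan
    margin = int(np.ceil(max_lag_samples)) + DEFAULT_RADIUS
    core = slice(margin, a.size - margin)
    grid = np.arange(-max_lag_samples, max_lag_samples + step / 2, step)
    best_r, best_d = -np.inf, 0.0
    for d in grid:
        r = _pearson(a[core], sinc_shift(b, float(d))[core])
        if r > best_r:
            best_r, best_d = r, float(d)
    return best_d
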