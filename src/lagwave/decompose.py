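"""Global / local signal split and the lag-only reconstruction.

The *global component* of a voxel is the OLS fit of its series on the global
ICs, each sinc-shifted by that voxel's mapped lag for that IC; the *local
component* is everything else (the residual plus the intercept), so
global + local reproduces the input exactly by construction.

The *lag-only reconstruction* rebuilds the global signal with a uniform
per-IC amplitude — the root mean square of the IC's mixing-matrix column —
so that only the lag structure, not the magnitude map, differs across voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .lagmap import LagMap
from .shift import sinc_shift
from .types import Dataset


@dataclass
class GlobalLocalDecomposition:
    global_: np.ndarray   # (V, T)
    local: np.ndarray     # (V, T)
    betas: np.ndarray     # (V, G), run-averaged; NaN where the IC was invalid
    relative_local_magnitude: float

    @property
    def total(self) -> np.ndarray:
        return self.global_ + self.local


@dataclass
class LagOnlyReconstruction:
    series: np.ndarray    # (V, T)
    weights: np.ndarray   # (G,) RMS of each mixing column
    valid: np.ndarray     # (V,) bool; False where no IC had a valid lag


def global_local_decompose(dataset: Dataset, global_ics: np.ndarray,
                           lag_maps: list[LagMap],
                           cond_limit: float = 1e8) -> GlobalLocalDecomposition:
    """Per-voxel, per-run OLS on the lag-shifted global ICs.

    The design holds an intercept plus one lag-shifted regressor per global
    IC with a valid lag at that voxel; the intercept belongs to the LOCAL
    component. ICs whose shifted copies are collinear at a voxel are dropped
    (later IC first) with a counted warning.
    """
    global_ics = np.atleast_2d(np.asarray(global_ics, float))
    G = global_ics.shape[0] if global_ics.size else 0
    V, T = dataset.data.shape
    if G == 0:
        return GlobalLocalDecomposition(
            global_=np.zeros((V, T)), local=dataset.data.copy(),
            betas=np.zeros((V, 0)), relative_local_magnitude=1.0)
    if len(lag_maps) != G:
        raise ValueError("one LagMap per global IC is required")
    tr = dataset.tr
    glob = np.zeros((V, T))
    betas = np.full((dataset.n_runs, V, G), np.nan)
    n_dropped = 0
    for ri, (a, b) in enumerate(dataset.run_bounds):
        ics_run = global_ics[:, a:b]
        Trun = b - a
        for v in range(V):
            cols, which = [], []
            for g in range(G):
                if lag_maps[g].valid[v]:
                    cols.append(sinc_shift(ics_run[g], lag_maps[g].lag[v] / tr))
                    which.append(g)
            if not cols:
                continue
            X = np.column_stack([np.ones(Trun)] + cols)
            while len(which) > 1 and np.linalg.cond(X) > cond_limit:
                X = X[:, :-1]
                which.pop()
                n_dropped += 1
            y = dataset.data[v, a:b]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            glob[v, a:b] = X[:, 1:] @ coef[1:]
            betas[ri, v, which] = coef[1:]
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} collinear shifted regressors", UserWarning)
    local = dataset.data - glob
    with np.errstate(invalid="ignore"):
        beta_avg = np.nanmean(betas, axis=0)
    total_rms = np.sqrt(np.mean(dataset.data ** 2))
    rel = float(np.sqrt(np.mean(local ** 2)) / total_rms) if total_rms > 0 else np.nan
    return GlobalLocalDecomposition(global_=glob, local=local, betas=beta_avg,
                                    relative_local_magnitude=rel)


def rms_mixing_weights(mixing: np.ndarray) -> np.ndarray:
    """Per-IC weight: root mean square of the mixing-matrix column."""
    mixing = np.atleast_2d(np.asarray(mixing, float))
    return np.sqrt(np.mean(mixing ** 2, axis=0))


def lag_only_reconstruct(global_ics: np.ndarray, lag_maps: list[LagMap],
                         mixing: np.ndarray,
                         run_bounds=None, tr: float = 0.72) -> LagOnlyReconstruction:
    """Rebuild the global signal keeping only its lag structure.

    series(v, .) = sum_i w_i * ic_i(t - lag_i(v)), with w_i the RMS of mixing
    column i: every voxel gets the same amplitude per IC. Voxels with no
    valid lag for any IC are flagged invalid and left zero.
    """
    global_ics = np.atleast_2d(np.asarray(global_ics, float))
    G, T = global_ics.shape
    if np.atleast_2d(mixing).shape[1] != G:
        raise ValueError("mixing columns must correspond to the global ICs")
    weights = rms_mixing_weights(mixing)
    V = lag_maps[0].lag.size
    bounds = run_bounds if run_bounds is not None else [(0, T)]
    out = np.zeros((V, T))
    valid_any = np.zeros(V, dtype=bool)
    for a, b in bounds:
        for g in range(G):
            seg = global_ics[g, a:b]
            lm = lag_maps[g]
            for v in np.flatnonzero(lm.valid):
                out[v, a:b] += weights[g] * sinc_shift(seg, lm.lag[v] / tr)
                valid_any[v] = True
    return LagOnlyReconstruction(series=out, weights=weights, valid=valid_any)
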