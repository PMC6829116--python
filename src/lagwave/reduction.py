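"""Spatial ICA parcellation and dual-regression stage 1.

Spatial ICA serves only as a functional parcellation that reduces the voxel
dimension before temporal ICA; independence is optimized over voxels. Stage 1
of dual regression then projects each volume onto the retained spatial maps
jointly (ordinary least squares per timepoint), yielding one "node" time
series per map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .types import Dataset, RunBounds


@dataclass
class SpatialICAResult:
    spatial_maps: np.ndarray          # (V, K), columns unit-normalized
    node_mixing: np.ndarray           # (T, K)
    k: int
    excluded: list[int] = field(default_factory=list)

    def retained_maps(self) -> np.ndarray:
        keep = [i for i in range(self.k) if i not in set(self.excluded)]
        return self.spatial_maps[:, keep]


@dataclass
class NodeTimeSeries:
    series: np.ndarray                # (T, K'), columns variance-normalized
    run_bounds: RunBounds
    tr: float


def spatial_ica(dataset: Dataset, k: int | str = "auto",
                explained_variance: float = 0.99,
                seed: int | None = 0, max_iter: int = 1000) -> SpatialICAResult:
    """Decompose the dataset into K spatially independent maps.

    With ``k='auto'`` the order is the number of principal components needed
    to reach the explained-variance threshold (default 99%) — appropriate for
    near-low-rank data; on noisy data pass an explicit ``k``.
    """
    X = dataset.data  # (V, T): samples are voxels -> spatial independence
    max_k = min(X.shape)
    if k == "auto":
        pca = PCA(n_components=min(max_k, X.shape[1] - 1), svd_solver="full")
        pca.fit(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, explained_variance) + 1)
        # guard against numerically null directions
        rank = int((pca.singular_values_ > 1e-10 * pca.singular_values_[0]).sum())
        if k > rank:
            warnings.warn(f"data rank {rank} below requested order; K reduced", UserWarning)
            k = rank
    k = int(k)
    if k > max_k:
        raise ValueError(f"K = {k} exceeds min(V, T) = {max_k}")
    ica = FastICA(n_components=k, fun="logcosh", algorithm="parallel",
                  whiten="unit-variance", random_state=seed, max_iter=max_iter)
    maps = ica.fit_transform(X)            # (V, K)
    node_mixing = ica.mixing_              # (T, K)
    norms = np.linalg.norm(maps, axis=0)
    maps = maps / norms
    node_mixing = node_mixing * norms
    return SpatialICAResult(spatial_maps=maps, node_mixing=node_mixing, k=k)


def exclude_components(result: SpatialICAResult, labels: list[int]) -> SpatialICAResult:
    """Flag spatial components as artifacts; they drop out of the design."""
    uniq = sorted(set(int(i) for i in labels))
    if len(uniq) != len(labels):
        warnings.warn("duplicate component indices in exclusion list; deduplicated",
                      UserWarning)
    for i in uniq:
        if not 0 <= i < result.k:
            raise IndexError(f"component index {i} outside [0, {result.k})")
    if len(uniq) == result.k:
        raise ValueError("cannot exclude every spatial component")
    return SpatialICAResult(spatial_maps=result.spatial_maps,
                            node_mixing=result.node_mixing,
                            k=result.k, excluded=uniq)


def dual_regression_stage1(dataset: Dataset, spatial_maps: np.ndarray,
                           normalize: bool = True) -> NodeTimeSeries:
    """Node time series: per-timepoint OLS of each volume on all maps jointly.

    Each column is variance-normalized over the whole concatenated series
    (FastICA downstream assumes comparable scales).
    """
    maps = np.asarray(spatial_maps, float)
    if maps.shape[0] != dataset.n_voxels:
        raise ValueError("spatial maps must live on the dataset voxel list")
    cond = np.linalg.cond(maps)
    if cond > 1e8:
        corr = np.corrcoef(maps.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"spatial maps are collinear (condition number {cond:.3g}); "
            f"most correlated pair: components {i} and {j} (r = {corr[i, j]:.4f})"
        )
    beta, *_ = np.linalg.lstsq(maps, dataset.data, rcond=None)  # (K', T)
    series = beta.T
    if normalize:
        sd = series.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        series = series / sd
    return NodeTimeSeries(series=series, run_bounds=list(dataset.run_bounds),
                          tr=dataset.tr)
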