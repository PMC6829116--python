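"""Temporal ICA with Icasso-style stability selection.

FastICA (tanh contrast, symmetric decorrelation) is run on the node time
series under repeated block-bootstrap resampling with fresh random
initializations; all source estimates are pooled, clustered by the absolute
correlation of their time courses, and each cluster is scored with the
stability index Iq = (average intra-cluster similarity) - (average
inter-cluster similarity). The model order is chosen as the dimension
yielding the most clusters with Iq > 0.5 (ties broken toward the smaller
order), and the reported components are the cluster centrotypes.

The FastICA core here keeps the whitening dimension (the node-space rank)
separate from the number of extracted components L. This matters for
stability selection: when L exceeds the number of genuine sources, the
surplus components must be free to wander in the residual subspace across
restarts and resamples — that wandering (low Iq) is what the counting rule
detects. An implementation that whitens to exactly L dimensions would pin
the surplus component to the deterministic orthogonal complement of the
sources and make it spuriously reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew

from .reduction import NodeTimeSeries

IQ_THRESHOLD = 0.5
DEFAULT_ESTIMATE_CAP = 5000


class _Whitener:
    """PCA whitening of (T, K') data to its numerical rank (or a given dim)."""

    def __init__(self, X: np.ndarray, dim: int | None = None):
        self.mean = X.mean(axis=0)
        Xc = X - self.mean
        cov = Xc.T @ Xc / Xc.shape[0]
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rank = int((evals > max(1e-12, 1e-10 * evals[0])).sum())
        d = rank if dim is None else min(dim, rank)
        self.dim = d
        self.evals = evals[:d]
        # rows of `forward` map data -> white space; `backward` de-whitens
        self.forward = (evecs[:, :d] / np.sqrt(evals[:d])).T   # (d, K')
        self.backward = evecs[:, :d] * np.sqrt(evals[:d])      # (K', d)

    def whiten(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.forward.T


def _symmetric_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^{-1/2} W, the symmetric (parallel) decorrelation step
    s, u = np.linalg.eigh(W @ W.T)
    return (u / np.sqrt(s)) @ u.T @ W


def _fastica_tanh(Z: np.ndarray, L: int, rng: np.random.Generator,
                  max_iter: int = 1000, tol: float = 1e-7) -> tuple[np.ndarray, bool]:
    """Symmetric FastICA with the tanh contrast on whitened data Z (T, d).

    Extracts L <= d orthonormal unmixing rows (L, d); the whitening dimension
    d is NOT collapsed to L. Returns (W, converged).
    """
    T, d = Z.shape
    if L > d:
        raise ValueError(f"cannot extract {L} components from rank-{d} data")
    W = _symmetric_decorrelate(rng.standard_normal((L, d)))
    converged = False
    for _ in range(max_iter):
        Y = Z @ W.T                      # (T, L) current source estimates
        G = np.tanh(Y)
        g_prime = 1.0 - G ** 2
        W_new = (G.T @ Z) / T - g_prime.mean(axis=0)[:, None] * W
        W_new = _symmetric_decorrelate(W_new)
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if delta < tol:
            converged = True
            break
    return W, converged


@dataclass
class TemporalICAResult:
    sources: np.ndarray   # (L, T), unit variance, skewness >= 0
    mixing: np.ndarray    # (K', L)
    converged: bool = True


@dataclass
class ClusterInfo:
    members: np.ndarray          # indices into the pooled estimate stack
    centrotype_index: int
    centrotype: np.ndarray       # (T,) unit-variance representative series
    iq: float


@dataclass
class StabilityEntry:
    L: int
    clusters: list[ClusterInfo]

    @property
    def n_reproducible(self) -> int:
        return sum(c.iq > IQ_THRESHOLD for c in self.clusters)

    def reproducible_components(self) -> np.ndarray:
        comps = [c.centrotype for c in self.clusters if c.iq > IQ_THRESHOLD]
        return np.stack(comps) if comps else np.empty((0, 0))


@dataclass
class StabilityReport:
    entries: dict[int, StabilityEntry] = field(default_factory=dict)
    chosen_L: int | None = None

    @property
    def components(self) -> np.ndarray:
        return self.entries[self.chosen_L].reproducible_components()


def _orient(sources: np.ndarray, mixing: np.ndarray | None = None):
    """Unit variance and non-negative skewness per source (sign convention)."""
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sources = sources / sd
    flip = np.where(skew(sources, axis=1) < 0, -1.0, 1.0)
    sources = sources * flip[:, None]
    if mixing is not None:
        mixing = mixing * (sd.ravel() * flip)[None, :]
        return sources, mixing
    return sources


def fastica_temporal(nodes: NodeTimeSeries, L: int, seed: int | None = 0,
                     max_iter: int = 1000, tol: float = 1e-7,
                     pca_dim: int | None = None) -> TemporalICAResult:
    """FastICA on node series, independence optimized along the time axis.

    The data are whitened to ``pca_dim`` dimensions (default: full numerical
    rank of the node space) and L components are extracted there.
    """
    X = nodes.series  # (T, K')
    if L > X.shape[1]:
        raise ValueError(f"L = {L} exceeds the {X.shape[1]} node series")
    wh = _Whitener(X, dim=pca_dim)
    Z = wh.whiten(X)
    rng = default_rng(seed)
    W, converged = _fastica_tanh(Z, L, rng, max_iter=max_iter, tol=tol)
    if not converged:
        warnings.warn("temporal FastICA did not converge", UserWarning)
    sources = (Z @ W.T).T                  # (L, T), unit variance (white data)
    mixing = wh.backward @ W.T             # (K', L)
    sources, mixing = _orient(sources, mixing)
    return TemporalICAResult(sources=sources, mixing=mixing, converged=converged)


def _block_bootstrap_index(T: int, run_bounds, block: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap: blocks drawn within runs, concatenated to T."""
    idx: list[np.ndarray] = []
    total = 0
    lengths = np.array([b - a for a, b in run_bounds], float)
    probs = lengths / lengths.sum()
    while total < T:
        ri = rng.choice(len(run_bounds), p=probs)
        a, b = run_bounds[ri]
        blk = min(block, b - a)
        start = a + rng.integers(0, b - a - blk + 1)
        idx.append(np.arange(start, start + blk))
        total += blk
    return np.concatenate(idx)[:T]


def iq_from_similarity(similarity: np.ndarray, cluster_ids: np.ndarray) -> np.ndarray:
    """Stability index per cluster from a pooled similarity matrix.

    Iq(c) = mean pairwise similarity within c (off-diagonal; 1.0 for a
    singleton) minus mean similarity between members of c and all
    non-members. Bounded in [-1, 1] for similarities in [0, 1].
    """
    S = np.asarray(similarity, float)
    ids = np.asarray(cluster_ids)
    iqs = []
    for c in np.unique(ids):
        inside = ids == c
        members = np.flatnonzero(inside)
        if members.size > 1:
            sub = S[np.ix_(members, members)]
            intra = sub[np.triu_indices(members.size, k=1)].mean()
        else:
            intra = 1.0
        outside = np.flatnonzero(~inside)
        inter = S[np.ix_(members, outside)].mean() if outside.size else 0.0
        iqs.append(intra - inter)
    return np.asarray(iqs)


def icasso_run(nodes: NodeTimeSeries, L: int, n_repeats: int,
               seed: int | None = 0, band_low: float = 0.01,
               estimate_cap: int = DEFAULT_ESTIMATE_CAP,
               max_iter: int = 1000, tol: float = 1e-6,
               pca_dim: int | None = None) -> StabilityEntry:
    """Pool FastICA estimates over bootstrap + random-restart repeats at one L.

    Each repeat draws a block bootstrap of the timepoints (block length one
    period of the lower band edge, respecting run boundaries and the series'
    autocorrelation) and a fresh random initialization; the learned unmixing
    is applied to the ORIGINAL series so estimates are comparable. Estimates
    are clustered by average linkage on 1 - |Pearson r| into L clusters.
    """
    if n_repeats < 2:
        raise ValueError("at least 2 repeats are required")
    if n_repeats * L > estimate_cap:
        raise ValueError(
            f"{n_repeats} repeats x {L} components = {n_repeats * L} estimates "
            f"exceeds the cap of {estimate_cap}; reduce repeats or the order"
        )
    X = nodes.series
    T = X.shape[0]
    block = max(1, int(round((1.0 / band_low) / nodes.tr)))
    ss = SeedSequence(seed)
    child = ss.spawn(n_repeats)
    estimates = []
    for rep in range(n_repeats):
        rng = default_rng(child[rep])
        idx = _block_bootstrap_index(T, nodes.run_bounds, block, rng)
        wh = _Whitener(X[idx], dim=pca_dim)
        W, _ = _fastica_tanh(wh.whiten(X[idx]), L, rng,
                             max_iter=max_iter, tol=tol)
        est = (wh.whiten(X) @ W.T).T      # (L, T) on the original timeline
        estimates.append(_orient(est))
    E = np.concatenate(estimates, axis=0)
    S = np.abs(np.corrcoef(E))
    np.clip(S, 0.0, 1.0, out=S)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    ids = fcluster(Z, t=L, criterion="maxclust")
    iqs = iq_from_similarity(S, ids)
    clusters = []
    for ci, c in enumerate(np.unique(ids)):
        members = np.flatnonzero(ids == c)
        sums = S[np.ix_(members, members)].sum(axis=1)
        centro = members[int(np.argmax(sums))]
        rep_series = _orient(E[centro][None, :])[0]
        clusters.append(ClusterInfo(members=members, centrotype_index=int(centro),
                                    centrotype=rep_series, iq=float(iqs[ci])))
    clusters.sort(key=lambda c: -c.iq)
    return StabilityEntry(L=L, clusters=clusters)


def select_model_order(nodes: NodeTimeSeries, L_range, n_repeats: int = 100,
                       seed: int | None = 0, **kwargs) -> StabilityReport:
    """Scan candidate orders; keep the one with the most reproducible clusters.

    Ties are broken toward the smallest order. Raises when no cluster at any
    order passes the Iq threshold.
    """
    L_values = sorted(int(L) for L in L_range)
    if not L_values:
        raise ValueError("L_range must be non-empty")
    ss = SeedSequence(seed)
    child = ss.spawn(len(L_values))
    report = StabilityReport()
    for i, L in enumerate(L_values):
        entry = icasso_run(nodes, L, n_repeats,
                           seed=int(child[i].generate_state(1)[0] % (2 ** 31)),
                           **kwargs)
        report.entries[L] = entry
    best = max(L_values, key=lambda L: (report.entries[L].n_reproducible, -L))
    if report.entries[best].n_reproducible == 0:
        raise ValueError("no reproducible decomposition: no cluster reached "
                         f"Iq > {IQ_THRESHOLD} at any scanned order")
    report.chosen_L = best
    return report
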