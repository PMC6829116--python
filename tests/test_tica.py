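"""Temporal ICA, Icasso stability clustering, Iq, model-order selection."""

import numpy as np
import pytest

import lagwave.tica as tica_mod
from lagwave import (fastica_temporal, generate_band_limited_source, icasso_run,
                     iq_from_similarity, make_node_fixture, select_model_order)
from lagwave.reduction import NodeTimeSeries
from lagwave.tica import StabilityEntry, ClusterInfo


def _nodes(sources, mixing, noise_sd, rng, run_len):
    X = (mixing @ sources).T
    if noise_sd:
        X = X + noise_sd * rng.standard_normal(X.shape)
    T = X.shape[0]
    bounds = [(i, min(i + run_len, T)) for i in range(0, T, run_len)]
    return NodeTimeSeries(series=X / X.std(axis=0), run_bounds=bounds, tr=0.72)


def _sources(n, T_run, n_runs, rng, depth=0.9):
    S = np.zeros((n, T_run * n_runs))
    for c in range(n):
        for r in range(n_runs):
            S[c, r * T_run:(r + 1) * T_run] = generate_band_limited_source(
                T_run, 0.72, rng=rng, modulation_depth=depth)
    return S


def _best_assignment(est, truth):
    from scipy.optimize import linear_sum_assignment
    M = np.abs(np.corrcoef(np.vstack([est, truth]))[:len(est), len(est):])
    ri, ci = linear_sum_assignment(-M)
    return M[ri, ci]


class TestFastICATemporal:
    def test_two_sources_recovered_from_random_mixing(self, rng):
        S = _sources(2, 600, 2, rng)
        nodes = _nodes(S, rng.normal(size=(10, 2)), 0.0, rng, 600)
        res = fastica_temporal(nodes, 2, seed=0)
        assert _best_assignment(res.sources, S).min() > 0.95

    def test_sources_pairwise_uncorrelated(self, rng):
        S = _sources(3, 600, 2, rng)
        nodes = _nodes(S, rng.normal(size=(8, 3)), 0.1, rng, 600)
        res = fastica_temporal(nodes, 3, seed=0)
        c = np.corrcoef(res.sources)
        off = np.abs(c[np.triu_indices(3, 1)])
        assert off.max() < 1e-6

    def test_rank_one_mixing(self, rng):
        S = _sources(1, 600, 1, rng)
        nodes = _nodes(S, np.ones((6, 1)), 0.0, rng, 600)
        res = fastica_temporal(nodes, 1, seed=0)
        assert abs(np.corrcoef(res.sources[0], S[0])[0, 1]) > 0.999

    def test_sources_skew_positive_unit_variance(self, rng):
        from scipy.stats import skew
        S = _sources(2, 600, 1, rng)
        nodes = _nodes(S, rng.normal(size=(6, 2)), 0.0, rng, 600)
        res = fastica_temporal(nodes, 2, seed=0)
        assert np.allclose(res.sources.std(axis=1), 1.0, atol=1e-8)
        assert (skew(res.sources, axis=1) >= 0).all()

    def test_mixing_reconstructs_nodes(self, rng):
        S = _sources(2, 600, 1, rng)
        nodes = _nodes(S, rng.normal(size=(6, 2)), 0.0, rng, 600)
        res = fastica_temporal(nodes, 2, seed=0)
        recon = (res.mixing @ res.sources).T
        centered = nodes.series - nodes.series.mean(axis=0)
        assert np.abs(recon - centered).max() < 1e-6

    def test_l_exceeding_nodes_rejected(self, rng):
        S = _sources(2, 600, 1, rng)
        nodes = _nodes(S, rng.normal(size=(4, 2)), 0.0, rng, 600)
        with pytest.raises(ValueError):
            fastica_temporal(nodes, 5)


class TestIq:
    def test_perfectly_isolated_cluster(self):
        # 2-member cluster with intra similarity 1, zero similarity elsewhere
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 1.0
        S[2, 3] = S[3, 2] = 1.0
        ids = np.array([1, 1, 2, 2])
        iqs = iq_from_similarity(S, ids)
        assert np.allclose(iqs, [1.0, 1.0])

    def test_definition_intra_minus_inter(self):
        # intra average 0.8, inter average 0.3 -> Iq = 0.5
        S = np.ones((4, 4))
        ids = np.array([1, 1, 2, 2])
        S[0, 1] = S[1, 0] = 0.8
        S[2, 3] = S[3, 2] = 0.8
        for i in (0, 1):
            for j in (2, 3):
                S[i, j] = S[j, i] = 0.3
        iqs = iq_from_similarity(S, ids)
        assert np.allclose(iqs, [0.5, 0.5])

    def test_bounds(self, rng):
        # random similarity matrices keep Iq within [-1, 1]
        for _ in range(20):
            n = rng.integers(4, 12)
            A = rng.uniform(0, 1, (n, n))
            S = (A + A.T) / 2
            np.fill_diagonal(S, 1.0)
            ids = rng.integers(1, 4, n)
            iqs = iq_from_similarity(S, ids)
            assert (iqs >= -1 - 1e-12).all() and (iqs <= 1 + 1e-12).all()


class TestIcasso:
    def test_strong_sources_all_reproducible(self, rng):
        S = _sources(3, 600, 2, rng)
        nodes = _nodes(S, rng.normal(size=(10, 3)), 0.0, rng, 600)
        entry = icasso_run(nodes, 3, 10, seed=0)
        assert all(c.iq > 0.9 for c in entry.clusters)

    def test_too_few_repeats_rejected(self, rng):
        S = _sources(2, 600, 1, rng)
        nodes = _nodes(S, rng.normal(size=(6, 2)), 0.0, rng, 600)
        with pytest.raises(ValueError):
            icasso_run(nodes, 2, 1)

    def test_estimate_cap_enforced(self, rng):
        S = _sources(2, 600, 1, rng)
        nodes = _nodes(S, rng.normal(size=(6, 2)), 0.0, rng, 600)
        with pytest.raises(ValueError, match="cap"):
            icasso_run(nodes, 2, 100, estimate_cap=50)

    def test_node_permutation_leaves_sources_and_iq_stable(self, rng):
        S = _sources(2, 600, 2, rng)
        A = rng.normal(size=(8, 2))
        nodes = _nodes(S, A, 0.0, rng, 600)
        perm = rng.permutation(8)
        nodes_p = NodeTimeSeries(series=nodes.series[:, perm],
                                 run_bounds=nodes.run_bounds, tr=nodes.tr)
        r1 = fastica_temporal(nodes, 2, seed=3)
        r2 = fastica_temporal(nodes_p, 2, seed=3)
        # sources agree up to sign/permutation; mixing rows are permuted
        M = np.abs(np.corrcoef(np.vstack([r1.sources, r2.sources]))[:2, 2:])
        if M[0, 0] > M[0, 1]:   # align component order of the two runs
            order = [0, 1]
        else:
            order = [1, 0]
        assert min(M[0, order[0]], M[1, order[1]]) > 0.99
        A1 = np.abs(r1.mixing)
        A2 = np.abs(r2.mixing[:, order])
        assert np.abs(A2 - A1[perm]).max() < 0.05


class TestModelOrderSelection:
    def test_argmax_with_tie_toward_smaller(self, monkeypatch, rng):
        def fake_icasso(nodes, L, n_repeats, seed=None, **kw):
            n_rep = {4: 3, 6: 5, 8: 5}[L]
            clusters = [ClusterInfo(members=np.array([0]), centrotype_index=0,
                                    centrotype=np.zeros(10), iq=0.9)
                        for _ in range(n_rep)]
            clusters += [ClusterInfo(members=np.array([0]), centrotype_index=0,
                                     centrotype=np.zeros(10), iq=0.1)
                         for _ in range(L - n_rep)]
            return StabilityEntry(L=L, clusters=clusters)

        monkeypatch.setattr(tica_mod, "icasso_run", fake_icasso)
        S = _sources(2, 300, 1, rng)
        nodes = _nodes(S, rng.normal(size=(8, 2)), 0.0, rng, 300)
        report = tica_mod.select_model_order(nodes, [4, 6, 8], n_repeats=5)
        assert report.chosen_L == 6

    def test_single_candidate_order(self, rng):
        S = _sources(2, 600, 1, rng)
        nodes = _nodes(S, rng.normal(size=(8, 2)), 0.0, rng, 600)
        report = select_model_order(nodes, [2], n_repeats=5, seed=0)
        assert report.chosen_L == 2

    def test_no_reproducible_decomposition_raises(self, monkeypatch, rng):
        def fake_icasso(nodes, L, n_repeats, seed=None, **kw):
            clusters = [ClusterInfo(members=np.array([0]), centrotype_index=0,
                                    centrotype=np.zeros(10), iq=0.2)
                        for _ in range(L)]
            return StabilityEntry(L=L, clusters=clusters)

        monkeypatch.setattr(tica_mod, "icasso_run", fake_icasso)
        S = _sources(2, 300, 1, rng)
        nodes = _nodes(S, rng.normal(size=(8, 2)), 0.0, rng, 300)
        with pytest.raises(ValueError, match="no reproducible"):
            tica_mod.select_model_order(nodes, [2, 3], n_repeats=5)

    def test_recovery_degrades_with_noise(self, rng):
        lo, hi = [], []
        for seed in range(6):
            r = np.random.default_rng(seed)
            S = _sources(3, 600, 1, r)
            A = r.normal(size=(8, 3))
            for noise, acc in ((0.0, lo), (2.0, hi)):
                nodes = _nodes(S, A, noise, r, 600)
                res = fastica_temporal(nodes, 3, seed=seed)
                acc.append(_best_assignment(res.sources, S).mean())
        assert np.mean(lo) > np.mean(hi)
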