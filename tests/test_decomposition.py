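"""Regularized NMF: graph, objective, updates, atlas fusion, parcellation."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import nnls

from pfntopo.decomposition import (UNASSIGNED, DecompositionConfig,
                                   build_locality_graph,
                                   decomposition_objective, derive_group_atlas,
                                   fit_individual, graph_degree,
                                   hard_parcellation, match_networks)
from pfntopo.qc import rescale_nonnegative
from pfntopo.synthetic import CohortConfig, make_sphere_mesh, simulate_cohort


class TestLocalityGraph:
    def test_identical_neighbors_weight_one(self, mesh_small):
        rng = np.random.default_rng(0)
        course = rng.standard_normal(30)
        ts = np.tile(course[:, None], (1, mesh_small.n_vertices))
        W = build_locality_graph(mesh_small, ts)
        coo = sp.triu(W, 1).tocoo()
        assert coo.nnz > 0
        np.testing.assert_allclose(coo.data, 1.0, atol=1e-12)

    def test_anticorrelated_neighbors_clipped(self, mesh_small):
        rng = np.random.default_rng(1)
        course = rng.standard_normal(30)
        signs = np.where(np.arange(mesh_small.n_vertices) % 2 == 0, 1.0, -1.0)
        ts = course[:, None] * signs[None, :]
        W = build_locality_graph(mesh_small, ts)
        # edges between opposite-sign vertices have correlation -1 -> weight 0
        coo = W.tocoo()
        opposite = signs[coo.row] * signs[coo.col] < 0
        assert not opposite.any()  # those edges were eliminated entirely

    def test_medial_wall_isolated(self, mesh_small):
        rng = np.random.default_rng(2)
        ts = rng.standard_normal((40, mesh_small.n_vertices))
        W = build_locality_graph(mesh_small, ts)
        deg = graph_degree(W)
        assert np.all(deg[mesh_small.medial_wall] == 0)

    def test_too_few_frames(self, mesh_small):
        with pytest.raises(ValueError):
            build_locality_graph(mesh_small, np.ones((1, mesh_small.n_vertices)))


class TestObjective:
    def test_vanishes_on_exact_factorization(self):
        rng = np.random.default_rng(3)
        U = rng.random((5, 2))
        V = rng.random((2, 8))
        W = sp.csr_matrix((8, 8))
        assert decomposition_objective(U @ V, U, V, V, W, alpha=1.0, beta=0.0) == 0.0

    def test_locality_null_space_constant_rows(self):
        # constant loadings within a connected component incur no penalty
        rng = np.random.default_rng(4)
        W = sp.csr_matrix(np.array([[0, 1.0], [1.0, 0]]))
        U = rng.random((4, 1))
        V = np.array([[0.7, 0.7]])
        X = U @ V
        f = decomposition_objective(X, U, V, V, W, alpha=0.0, beta=5.0)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_toy_matches_hand_arithmetic(self):
        # 2 vertices, 2 frames, K=1, every term computed by hand
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        U = np.array([[1.0], [2.0]])
        V = np.array([[1.5, 0.5]])
        Vg = np.array([[1.0, 1.0]])
        W = sp.csr_matrix(np.array([[0.0, 0.8], [0.8, 0.0]]))
        alpha, beta = 2.0, 3.0
        resid = X - U @ V
        expected = (resid**2).sum()                      # data term
        expected += alpha * (((V - Vg)**2).sum())        # consensus
        expected += beta * 0.8 * (1.5 - 0.5)**2          # sum_w w_uv (V_u-V_v)^2
        got = decomposition_objective(X, U, V, Vg, W, alpha, beta)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            decomposition_objective(np.ones((3, 4)), np.ones((3, 2)),
                                    np.ones((2, 5)))


def _subject_matrix(mesh, seed, K=4, T=40):
    cfg = CohortConfig(n_subjects=1, K=K, T=T, seed=seed)
    subjects, truth, _ = simulate_cohort(cfg, mesh=mesh)
    return rescale_nonnegative(subjects[0].time_series), truth


class TestFitIndividual:
    def test_objective_monotone(self, mesh_small):
        for seed in range(5):
            X, truth = _subject_matrix(mesh_small, seed)
            W = build_locality_graph(mesh_small, X)
            cfg = DecompositionConfig(K=4, max_iter=60)
            _, _, trace = fit_individual(X, truth.group_atlas, W, cfg)
            d = np.diff(trace.objective)
            assert np.all(d <= 1e-12 * trace.objective[:-1])

    def test_noiseless_disjoint_support_recovery(self):
        # two networks on disjoint vertex sets with distinct time courses
        rng = np.random.default_rng(5)
        N, T = 20, 60
        V_true = np.zeros((2, N))
        V_true[0, :10] = rng.uniform(0.5, 1.0, 10)
        V_true[1, 10:] = rng.uniform(0.5, 1.0, 10)
        # temporal factor already in [0, 1] so X needs no per-vertex rescale
        # (which would flatten within-network amplitude structure)
        U_raw = np.abs(rng.standard_normal((T, 2)))
        U_true = U_raw / U_raw.max(axis=0)
        X = U_true @ V_true
        Vg = V_true + 0.05  # slightly perturbed initialization atlas
        W = sp.csr_matrix((N, N))
        cfg = DecompositionConfig(alpha=0.01, beta=0.0, K=2, max_iter=500)
        _, V, _ = fit_individual(X, Vg, W, cfg)
        _, mc = match_networks(V, V_true)
        assert mc > 0.99

    def test_consensus_dominated_limit(self, mesh_small, atlas_small):
        X, _ = _subject_matrix(mesh_small, 11, K=6)
        W = build_locality_graph(mesh_small, X)
        cfg = DecompositionConfig(alpha=1e6, beta=0.0, K=6, max_iter=200)
        _, V, _ = fit_individual(X, atlas_small, W, cfg)
        rel = np.linalg.norm(V - atlas_small) / np.linalg.norm(atlas_small)
        assert rel < 1e-3

    def test_nonnegativity_closed(self, mesh_small):
        X, truth = _subject_matrix(mesh_small, 13)
        W = build_locality_graph(mesh_small, X)
        U, V, _ = fit_individual(X, truth.group_atlas, W,
                                 DecompositionConfig(K=4, max_iter=30))
        assert U.min() >= 0 and V.min() >= 0

    def test_rejects_negative_input(self, mesh_small, atlas_small):
        X = -np.ones((10, mesh_small.n_vertices))
        W = sp.csr_matrix((mesh_small.n_vertices, mesh_small.n_vertices))
        with pytest.raises(ValueError):
            fit_individual(X, atlas_small, W)

    def test_reduces_to_plain_nmf(self):
        # alpha=beta=0 must follow the classical multiplicative updates:
        # compare the whole objective trajectory against an independently
        # coded oracle started from the same initialization.
        rng = np.random.default_rng(17)
        X = rescale_nonnegative(rng.random((5, 8)))
        Vg = rng.uniform(0.2, 1.0, size=(2, 8))
        eps = 1e-10
        U = np.vstack([nnls(Vg.T, X[t])[0] for t in range(5)])
        V = Vg.copy()
        oracle = [np.linalg.norm(X - U @ V, "fro")**2]
        for _ in range(40):
            U = U * (X @ V.T) / (U @ V @ V.T + eps)
            V = V * (U.T @ X) / (U.T @ U @ V + eps)
            oracle.append(np.linalg.norm(X - U @ V, "fro")**2)
        cfg = DecompositionConfig(alpha=0.0, beta=0.0, K=2, max_iter=40,
                                  rel_tol=1e-300)
        W = sp.csr_matrix((8, 8))
        _, _, trace = fit_individual(X, Vg, W, cfg)
        np.testing.assert_allclose(trace.objective, oracle, rtol=1e-10)

    def test_consensus_pull_monotone_in_alpha(self, mesh_small, atlas_small):
        dists = {a: [] for a in (0.1, 1.0, 10.0, 1e3, 1e6)}
        for seed in range(3):
            X, _ = _subject_matrix(mesh_small, 50 + seed, K=6)
            W = build_locality_graph(mesh_small, X)
            for a in dists:
                cfg = DecompositionConfig(alpha=a, beta=0.0, K=6, max_iter=150)
                _, V, _ = fit_individual(X, atlas_small, W, cfg)
                dists[a].append(np.linalg.norm(V - atlas_small))
        means = [np.mean(dists[a]) for a in sorted(dists)]
        assert all(x >= y - 1e-9 for x, y in zip(means, means[1:]))


class TestDeriveGroupAtlas:
    def test_single_run_passthrough(self, mesh_small):
        subjects = [_subject_matrix(mesh_small, s)[0] for s in range(3)]
        cfg = DecompositionConfig(K=3)
        atlas = derive_group_atlas(subjects, cfg, n_runs=1, seed=2)
        assert atlas.shape == (3, mesh_small.n_vertices)
        assert atlas.min() >= 0

    def test_deterministic(self, mesh_small):
        subjects = [_subject_matrix(mesh_small, s)[0] for s in range(4)]
        cfg = DecompositionConfig(K=3)
        A = derive_group_atlas(subjects, cfg, n_runs=3, seed=9)
        B = derive_group_atlas(subjects, cfg, n_runs=3, seed=9)
        np.testing.assert_array_equal(A, B)

    def test_recovers_generative_atlas(self):
        mesh = make_sphere_mesh(3, two_hemispheres=False)
        cfg = CohortConfig(n_subjects=20, K=8, T=150, topography_jitter=0.1,
                           noise_sd=0.1, seed=5)
        subjects, truth, _ = simulate_cohort(cfg, mesh=mesh)
        data = [rescale_nonnegative(s.time_series) for s in subjects]
        atlas = derive_group_atlas(data, DecompositionConfig(K=8), n_runs=5,
                                   seed=7)
        _, mc = match_networks(atlas, truth.group_atlas)
        assert mc > 0.9


class TestHardParcellation:
    def test_one_hot_reproduces_support(self):
        V = np.eye(3)[:, [0, 1, 2, 1, 0]]
        np.testing.assert_array_equal(hard_parcellation(V), [0, 1, 2, 1, 0])

    def test_tie_breaks_to_lowest_index(self):
        V = np.zeros((6, 1))
        V[2, 0] = V[5, 0] = 0.4
        assert hard_parcellation(V)[0] == 2

    def test_zero_column_unassigned(self):
        V = np.array([[1.0, 0.0], [0.5, 0.0]])
        assert hard_parcellation(V)[1] == UNASSIGNED
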