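"""Embedding suite: analytic oracles, recovery checks, invariances."""

import itertools

import numpy as np
import pytest
import scipy.linalg
from scipy.sparse import csgraph
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

import connectopy as cp
from connectopy.embeddings import (
    DiffusionMapGradients,
    IsomapGradients,
    KernelPCAGradients,
    _laplacian_eigenmaps,
)
from connectopy.graphs import DisconnectedGraphError, NeighborhoodGraph


def _path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return NeighborhoodGraph(a, "knn_unweighted", False, {})


def _matched_abs_r(emb, coords):
    return cp.prediction_accuracy(emb, coords)


class TestSpectral:
    def test_path_graph_first_component_monotone(self):
        res = cp.spectral_embed(_path_graph(6))
        first = res.components[:, 0]
        diffs = np.diff(first)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_constant_direction_excluded(self):
        """The trivial D^{1/2}*1 eigenvector (eigenvalue 0) is dropped: the
        returned eigenvalues are strictly positive and components are
        orthogonal to D^{1/2}*1."""
        g = _path_graph(8)
        res = cp.spectral_embed(g)
        assert np.all(res.diagnostics["eigenvalues"] > 1e-10)
        # generalized eigenvectors are D-orthogonal to the constant vector
        deg = g.affinity.sum(axis=1)
        assert np.allclose(res.components.T @ deg, 0.0, atol=1e-8)

    def test_disconnected_graph_rejected(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        a = scipy.linalg.block_diag(tri, tri)
        with pytest.raises(DisconnectedGraphError):
            cp.spectral_embed(NeighborhoodGraph(a, "knn_unweighted", False, {}))

    def test_sparse_solver_matches_dense_oracle(self):
        """The iterative eigensolver path agrees with a full dense
        eigendecomposition (eigenvalues 1e-8, eigenvectors up to sign)."""
        import connectopy.embeddings as emb_mod

        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        g = cp.knn_graph(X, k=6, weighted=True)
        dense = cp.spectral_embed(g)
        old = emb_mod._DENSE_EIG_MAX
        emb_mod._DENSE_EIG_MAX = 0  # force the ARPACK shift-invert path
        try:
            sparse = cp.spectral_embed(g)
        finally:
            emb_mod._DENSE_EIG_MAX = old
        assert np.allclose(
            dense.diagnostics["eigenvalues"], sparse.diagnostics["eigenvalues"],
            atol=1e-8,
        )
        for j in range(2):
            r = abs(pearsonr(dense.components[:, j], sparse.components[:, j]).statistic)
            assert r > 1 - 1e-8

    def test_estimator_recovers_grid(self, grid_coords):
        emb = cp.SpectralGradients(variant="knn_unweighted", k=8).fit_transform(grid_coords)
        acc = _matched_abs_r(emb, grid_coords)
        assert min(acc.values()) >= 0.9


class TestLinear:
    def test_pca_recovers_planted_plane(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal((50, 2))
        basis = np.linalg.qr(rng.standard_normal((6, 6)))[0][:, :2]
        X = latent @ basis.T  # noiseless 2-D subspace in 6 dims
        emb = cp.pca_embed(X).components
        _, _, disparity = procrustes(latent - latent.mean(0), emb)
        assert disparity < 1e-6

    def test_pca_scores_uncorrelated(self, small_fingerprints):
        emb = cp.pca_embed(small_fingerprints.values).components
        assert abs(np.cov(emb.T)[0, 1]) < 1e-8 * np.var(emb[:, 0])

    def test_ica_unmixes_sources(self):
        rng = np.random.default_rng(2)
        s = np.column_stack([
            rng.uniform(-1, 1, 3000),
            rng.laplace(size=3000),
        ])
        X = s @ np.array([[1.0, 0.4], [0.3, 1.0]]).T
        emb = cp.ica_embed(X, seed=0).components
        cmat = np.abs(np.corrcoef(emb.T, s.T)[:2, 2:])
        # each recovered component matches one true source almost perfectly
        assert cmat.max(axis=1).min() > 0.99

    def test_rank_deficient_rejected(self):
        X = np.outer(np.arange(10.0), np.ones(4))  # rank 1 after centering
        with pytest.raises(ValueError):
            cp.pca_embed(X)


class TestKernelPCA:
    def test_poly2_matches_explicit_kernel_eigendecomposition(self):
        """Oracle: build K = (XX' + 1)^2 by hand, double-center, eigen-
        decompose, and compare projections up to sign."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 4))
        K = (X @ X.T + 1.0) ** 2
        n = K.shape[0]
        H = np.eye(n) - np.ones((n, n)) / n
        Kc = H @ K @ H
        vals, vecs = np.linalg.eigh(Kc)
        oracle = vecs[:, ::-1][:, :2] * np.sqrt(vals[::-1][:2])
        emb = cp.kpca_embed(X, kernel="poly2").components
        for j in range(2):
            r = abs(pearsonr(emb[:, j], oracle[:, j]).statistic)
            assert r > 1 - 1e-8

    def test_rbf_self_similarity_invariance(self):
        """exp(-gamma*0)=1 for any gamma: duplicating a sample leaves the
        two duplicates at identical embedding coordinates."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 3))
        X[5] = X[0]
        for gamma in (0.01, 1.0, 50.0):
            emb = cp.kpca_embed(X, kernel="rbf", gamma=gamma).components
            assert np.allclose(emb[0], emb[5], atol=1e-8)

    def test_invalid_kernel(self):
        with pytest.raises(ValueError, match="kernel"):
            cp.kpca_embed(np.random.default_rng(0).normal(size=(10, 3)), kernel="sigmoid")


@pytest.fixture(scope="module")
def lifted_sheet(grid_coords):
    """The 12 x 10 grid lifted into 5-D with mild curvature: a noise-free
    2-D manifold that is not trivially flat (LTSA's alignment problem is
    degenerate on an exactly planar input)."""
    u, v = grid_coords[:, 0], grid_coords[:, 1]
    return np.column_stack(
        [u, v, 0.5 * np.sin(u / 3), 0.5 * np.cos(v / 3), 0.01 * u * v]
    )


@pytest.mark.parametrize("embed", [cp.mlle_embed, cp.ltsa_embed], ids=["mlle", "ltsa"])
class TestLocalLinearFamily:
    def test_grid_recovery(self, embed, lifted_sheet, grid_coords):
        emb = embed(lifted_sheet, k=10).components
        acc = _matched_abs_r(emb, grid_coords)
        assert min(acc.values()) >= 0.9

    def test_shape(self, embed):
        X = np.random.default_rng(5).standard_normal((20, 6))
        assert embed(X, k=8).components.shape == (20, 2)

    def test_translation_invariance(self, embed, lifted_sheet):
        a = embed(lifted_sheet, k=10).components
        b = embed(lifted_sheet + 100.0, k=10).components
        _, _, disparity = procrustes(a, b)
        assert disparity < 1e-6

    def test_k_too_small(self, embed):
        with pytest.raises(ValueError):
            embed(np.random.default_rng(0).normal(size=(15, 4)), k=2)


class TestIsomap:
    def test_collinear_ordering(self):
        X = np.column_stack([np.arange(5.0), np.zeros(5)])
        emb = cp.isomap_embed(X, k=2).components
        rho = spearmanr(emb[:, 0], np.arange(5)).statistic
        assert abs(rho) > 1 - 1e-9

    def test_geodesic_at_least_euclidean(self, grid_coords):
        iso = IsomapGradients(k=6).fit(grid_coords)
        # recompute the geodesics independently: kNN distance graph + dijkstra
        d = squareform(pdist(grid_coords))
        nn = np.argsort(d + np.eye(len(d)) * 1e9, axis=1)[:, :6]
        sparse = np.zeros_like(d)
        rows = np.repeat(np.arange(len(d)), 6)
        sparse[rows, nn.ravel()] = d[rows, nn.ravel()]
        geo = csgraph.shortest_path(sparse, method="D", directed=False)
        assert np.all(geo >= d - 1e-9)

    def test_dijkstra_matches_exhaustive_enumeration(self):
        """n <= 12 oracle: shortest paths equal brute-force minimization
        over all simple paths."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((7, 2))
        g = cp.knn_graph(X, k=2)
        d = squareform(pdist(X))
        w = np.where(g.affinity > 0, d, 0.0)
        dij = csgraph.shortest_path(w, method="D", directed=False)

        def brute(i, j):
            best = np.inf
            nodes = [v for v in range(7) if v not in (i, j)]
            for r in range(len(nodes) + 1):
                for mid in itertools.permutations(nodes, r):
                    path = (i, *mid, j)
                    if all(w[a, b] > 0 for a, b in zip(path, path[1:])):
                        best = min(best, sum(w[a, b] for a, b in zip(path, path[1:])))
            return best

        for i in range(7):
            for j in range(i + 1, 7):
                assert np.isclose(dij[i, j], brute(i, j))

    def test_complete_graph_reduces_to_mds(self):
        """With k = n-1 every geodesic is the single-hop Euclidean distance,
        so Isomap equals classical MDS of X, i.e. PCA scores."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((15, 4))
        iso = cp.isomap_embed(X, k=14).components
        pca = cp.pca_embed(X).components
        for j in range(2):
            assert abs(pearsonr(iso[:, j], pca[:, j]).statistic) > 1 - 1e-6

    def test_disconnected_rejected(self):
        X = np.vstack([np.zeros((3, 2)) + np.eye(3, 2), 100 + np.eye(3, 2)])
        with pytest.raises(DisconnectedGraphError):
            cp.isomap_embed(X, k=1)


class TestDiffusionMaps:
    def _dense_oracle(self, X, k, eps, alpha):
        """Independent dense computation of the diffusion-map components."""
        d2 = squareform(pdist(X, "sqeuclidean"))
        g = cp.knn_graph(X, k)
        mask = (g.affinity > 0) | np.eye(len(X), dtype=bool)
        K = np.where(mask, np.exp(-d2 / eps), 0.0)
        q = K.sum(1)
        Ka = K / np.outer(q**alpha, q**alpha)
        P = Ka / Ka.sum(1, keepdims=True)
        vals, vecs = scipy.linalg.eig(P)
        order = np.argsort(-vals.real)
        return vals.real[order], vecs.real[:, order]

    def test_transition_matrix_properties(self):
        """Rows of P sum to one and the leading eigenvalue is 1 with a
        constant right eigenvector."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3))
        vals, vecs = self._dense_oracle(X, k=5, eps=2.0, alpha=0.5)
        assert np.isclose(vals[0], 1.0, atol=1e-10)
        lead = vecs[:, 0]
        assert np.allclose(lead / lead[0], 1.0, atol=1e-8)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 4))
        emb = cp.diffusion_embed(X, k=6, eps_diff=3.0, alpha=0.5).components
        vals, vecs = self._dense_oracle(X, k=6, eps=3.0, alpha=0.5)
        for j in range(2):
            r = abs(pearsonr(emb[:, j], vecs[:, j + 1]).statistic)
            assert r > 1 - 1e-8

    def test_blob_separation(self):
        """Two tight blobs bridged by one midpoint: the first non-trivial
        eigenvector separates the blobs by sign."""
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.05, size=(8, 2))
        b = rng.normal(0, 0.05, size=(8, 2)) + [10.0, 0.0]
        bridge = np.array([[5.0, 0.0]])
        X = np.vstack([a, b, bridge])
        emb = cp.diffusion_embed(X, k=8, eps_diff=30.0, alpha=0.5).components
        first = emb[:, 0]
        assert len(set(np.sign(first[:8]))) == 1
        assert len(set(np.sign(first[8:16]))) == 1
        assert np.sign(first[0]) != np.sign(first[8])

    def test_disconnected_rejected(self):
        X = np.vstack([np.eye(3, 2), 100 + np.eye(3, 2)])
        with pytest.raises(DisconnectedGraphError):
            cp.diffusion_embed(X, k=1, eps_diff=1.0)


class TestTSNE:
    def test_argmin_and_determinism(self, grid_coords):
        est = cp.TSNEGradients(perplexity=20, learning_rate=200, seed=5, n_restarts=3)
        emb1 = est.fit_transform(grid_coords)
        diag = est.diagnostics_
        assert diag["kl_divergence"] == min(diag["all_kl"])
        emb2 = cp.TSNEGradients(
            perplexity=20, learning_rate=200, seed=5, n_restarts=3
        ).fit_transform(grid_coords)
        assert np.array_equal(emb1, emb2)

    def test_grid_recovery(self, grid_coords):
        emb = cp.tsne_embed(
            grid_coords, perplexity=30, learning_rate=500, seed=0
        ).components
        acc = _matched_abs_r(emb, grid_coords)
        assert min(acc.values()) >= 0.8

    def test_perplexity_bound(self):
        with pytest.raises(ValueError, match="perplexity"):
            cp.tsne_embed(np.random.default_rng(0).normal(size=(10, 3)), perplexity=10)


def test_sign_flip_leaves_accuracy_unchanged(grid_coords):
    """Negating any embedding column is invisible to the benchmark."""
    emb = cp.pca_embed(grid_coords).components
    base = cp.prediction_accuracy(emb, grid_coords)
    for j in (0, 1):
        flipped = emb.copy()
        flipped[:, j] = -flipped[:, j]
        acc = cp.prediction_accuracy(flipped, grid_coords)
        assert acc == pytest.approx(base)
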