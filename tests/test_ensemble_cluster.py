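import numpy as np
import pytest

from scrden import ValidationError
from scrden.ensemble_cluster import (ClusterAssignment, cluster_cells,
                                     eigengap_cluster_count, embed_views,
                                     fuse_views, local_scaling_kernel,
                                     spectral_cluster)
from scrden.rank_network import EdgeProfileMatrix
from scrden.metrics import clustering_agreement

from _oracles import local_kernel_oracle


def profiles_from(values):
    values = np.asarray(values, dtype=float)
    return EdgeProfileMatrix(
        [("a", f"b{i}") for i in range(values.shape[0])], values,
        [f"c{j}" for j in range(values.shape[1])], normalization="minmax")


def planted_affinity(sizes, seed, w_in=1.0, w_out=0.05, noise=0.02):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    E = np.full((n, n), w_out)
    start = 0
    for s in sizes:
        E[start:start + s, start:start + s] = w_in
        start += s
    E = E + rng.uniform(0, noise, (n, n))
    E = (E + E.T) / 2
    np.fill_diagonal(E, 0.0)
    return E


class TestLocalScalingKernel:
    def test_rows_stochastic_with_half_diagonal(self, rng):
        coords = rng.normal(size=(40, 3))
        _, P, S = local_scaling_kernel(coords, k=5, mu=0.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(P), 0.5, atol=1e-15)
        np.testing.assert_allclose(S.sum(axis=1), 0.5, atol=1e-12)

    def test_five_point_configuration_matches_double_loop(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 2.0],
                           [4.0, 4.0], [5.0, 3.5]])
        W, P, S = local_scaling_kernel(coords, k=2, mu=0.7)
        Wo, Po, So = local_kernel_oracle(coords, k=2, mu=0.7)
        np.testing.assert_allclose(W, Wo, atol=1e-10)
        np.testing.assert_allclose(P, Po, atol=1e-10)
        np.testing.assert_allclose(S, So, atol=1e-10)

    def test_duplicate_points_survive_scale_floor(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        _, P, _ = local_scaling_kernel(coords, k=1, mu=0.5)
        assert np.isfinite(P).all()

    @pytest.mark.parametrize("k,mu", [(0, 0.5), (10, 0.5), (2, 0.0)])
    def test_invalid_parameters(self, k, mu):
        with pytest.raises(ValidationError):
            local_scaling_kernel(np.zeros((5, 2)), k=k, mu=mu)


class TestEmbedViews:
    def test_seed_reproducibility(self, rng):
        prof = profiles_from(rng.random((15, 30)))
        e1 = embed_views(prof, seed=3)
        e2 = embed_views(prof, seed=3)
        np.testing.assert_array_equal(e1.tsne, e2.tsne)
        np.testing.assert_array_equal(e1.umap, e2.umap)
        np.testing.assert_array_equal(e1.pca, e2.pca)

    def test_duplicate_cells_identical_pca(self, rng):
        values = rng.random((10, 20))
        values[:, 1] = values[:, 0]
        emb = embed_views(profiles_from(values), seed=0)
        np.testing.assert_allclose(emb.pca[0], emb.pca[1], atol=1e-10)

    def test_rank_one_matrix_single_pca_direction(self):
        values = np.outer(np.ones(6), np.linspace(0, 1, 20))
        emb = embed_views(profiles_from(values), seed=0)
        assert np.abs(emb.pca[:, 1:]).max() < 1e-10

    def test_too_few_cells(self):
        with pytest.raises(ValidationError):
            embed_views(profiles_from(np.ones((4, 2))), seed=0)


class TestFusion:
    def _kernels(self, coords_list, k=5, mu=0.5):
        return [local_scaling_kernel(c, k, mu)[1:] for c in coords_list]

    def test_infinite_tolerance_returns_mean_of_initial(self, rng):
        coords = [rng.normal(size=(20, 2)) for _ in range(3)]
        kernels = self._kernels(coords)
        E, n_iter = fuse_views(kernels, iters_max=10, tol=np.inf)
        mean_P = sum(P for P, _ in kernels) / 3
        np.testing.assert_allclose(E, (mean_P + mean_P.T) / 2, atol=1e-12)
        assert n_iter == 0

    def test_single_view_rejected(self, rng):
        kernels = self._kernels([np.random.default_rng(0).normal(size=(10, 2))])
        with pytest.raises(ValidationError):
            fuse_views(kernels)

    def test_one_dense_iteration_matches_matrix_product_oracle(self, rng):
        coords = [rng.normal(size=(12, 2)) for _ in range(2)]
        # k = n-1: the sparse kernel has full support
        kernels = self._kernels(coords, k=11)
        P = [np.array(p) for p, _ in kernels]
        S = [np.array(s) for _, s in kernels]
        E, n_iter = fuse_views(kernels, iters_max=1, tol=1e-15)
        expected = []
        for v in range(2):
            cross = P[1 - v]
            upd = S[v] @ cross @ S[v].T
            upd = (upd + upd.T) / 2
            off = upd.copy()
            np.fill_diagonal(off, 0.0)
            off = off / (2.0 * off.sum(axis=1, keepdims=True))
            np.fill_diagonal(off, 0.5)
            expected.append(off)
        Em = sum(expected) / 2
        np.testing.assert_allclose(E, (Em + Em.T) / 2, atol=1e-10)

    def test_block_structure_preserved(self, rng):
        E0 = planted_affinity([10, 10], seed=0, w_out=0.0, noise=0.0)
        coords = np.vstack([rng.normal(0, 0.1, (10, 2)),
                            rng.normal(8, 0.1, (10, 2))])
        kernels = self._kernels([coords, coords, coords], k=5)
        E, _ = fuse_views(kernels, iters_max=20, tol=1e-8)
        cross = E[:10, 10:]
        assert cross.max() < 1e-6
        assert (E0[:10, :10] >= 0).all()  # planted blocks sanity

    def test_row_stochastic_at_every_iteration(self, rng):
        coords = [rng.normal(size=(25, 2)) for _ in range(3)]
        kernels = self._kernels(coords)
        _, _, history = fuse_views(kernels, iters_max=8, tol=0.0,
                                   return_history=True)
        assert len(history) > 1
        for views in history:
            for P in views:
                np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
                np.testing.assert_allclose(np.diag(P), 0.5, atol=1e-12)

    def test_invariant_under_simultaneous_cell_permutation(self, rng):
        coords = [rng.normal(size=(15, 2)) for _ in range(3)]
        kernels = self._kernels(coords)
        E, _ = fuse_views(kernels, iters_max=5, tol=0.0)
        perm = rng.permutation(15)
        kernels_p = self._kernels([c[perm] for c in coords])
        Ep, _ = fuse_views(kernels_p, iters_max=5, tol=0.0)
        np.testing.assert_allclose(Ep, E[np.ix_(perm, perm)], atol=1e-9)


class TestEigengap:
    def test_exact_three_blocks_dominant_gap(self):
        E = planted_affinity([8, 8, 8], seed=0, w_out=0.0, noise=0.0)
        p, lam, gaps = eigengap_cluster_count(E)
        assert np.sum(np.abs(lam) < 1e-8) == 3
        idx = np.arange(2, 2 + len(gaps))
        assert idx[np.argmax(gaps)] == 3

    @pytest.mark.parametrize("sizes,expected", [
        ([10, 25, 25], 3),
        ([6, 6, 29, 29], 4),
    ])
    def test_planted_recovery(self, sizes, expected):
        E = planted_affinity(sizes, seed=0)
        p, _, _ = eigengap_cluster_count(E)
        assert p == expected

    def test_asymmetric_matrix_rejected(self):
        E = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValidationError):
            eigengap_cluster_count(E)


class TestSpectralCluster:
    def test_single_cluster(self):
        E = planted_affinity([6], seed=0)
        labels = spectral_cluster(E, 1, seed=0)
        assert set(labels.labels) == {1}

    def test_two_planted_blocks_recovered_exactly(self):
        E = planted_affinity([12, 8], seed=1)
        labels = spectral_cluster(E, 2, seed=0)
        truth = [0] * 12 + [1] * 8
        ari, _ = clustering_agreement(truth, labels.labels)
        assert ari == pytest.approx(1.0)
        # relabeled by decreasing size: the 12-block is cluster 1
        assert labels.labels[0] == 1

    def test_permutation_equivariance(self, rng):
        E = planted_affinity([10, 10], seed=2)
        labels = spectral_cluster(E, 2, seed=0).labels
        perm = rng.permutation(20)
        labels_p = spectral_cluster(E[np.ix_(perm, perm)], 2, seed=0).labels
        ari, _ = clustering_agreement(labels[perm], labels_p)
        assert ari == pytest.approx(1.0)

    def test_too_many_clusters(self):
        with pytest.raises(ValidationError):
            spectral_cluster(np.ones((4, 4)), 5, seed=0)


class TestClusterCells:
    def test_user_override_fixes_cluster_count(self, rng):
        values = rng.random((30, 60))
        prof = profiles_from(values)
        labels, fused, _ = cluster_cells(prof, k=10, n_clusters=4, seed=0)
        assert labels.n_clusters == 4
        assert fused.n_clusters == 4
        np.testing.assert_allclose(fused.E, fused.E.T, atol=1e-12)
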