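import numpy as np
import pytest
from scipy.optimize import brentq

from gradspike import (
    UmapConfig, cross_entropy, fuzzy_graph, knn_distances, local_scales,
    low_dim_similarity, membership_strengths, optimize_embedding, symmetrize,
    umap_embed,
)


class TestKnnDistances:
    def test_hand_geometry_on_a_line(self):
        X = np.array([[0.0], [1.0], [3.0], [7.0]])
        nbrs, _ = knn_distances(X, k=1)
        assert nbrs[:, 0].tolist() == [1, 0, 1, 2]

    def test_duplicate_points_are_mutual_zero_distance(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        nbrs, dists = knn_distances(X, k=1)
        assert nbrs[0, 0] == 1 and nbrs[1, 0] == 0
        assert dists[0, 0] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((100, 5))
        k = 7
        nbrs, dists = knn_distances(X, k)
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.fill_diagonal(D, np.inf)
        for i in range(100):
            order = np.argsort(D[i], kind="stable")[:k]
            assert nbrs[i].tolist() == order.tolist()
            assert np.allclose(dists[i], D[i][order])


class TestLocalScales:
    def test_sigma_against_scalar_root_finder(self):
        # distances [1,2,3,4], k=4: rho=1 and sigma solves
        # e^0 + e^(-1/s) + e^(-2/s) + e^(-3/s) = log2(4) = 2
        d = np.array([[1.0, 2.0, 3.0, 4.0]])
        rho, sigma, flags = local_scales(d, k=4)
        assert rho[0] == 1.0
        oracle = brentq(
            lambda s: sum(np.exp(-x / s) for x in (0.0, 1.0, 2.0, 3.0)) - 2.0,
            1e-6, 1e3, xtol=1e-12)
        assert sigma[0] == pytest.approx(oracle, abs=1e-4)
        assert not flags[0]
        assert 1.5 < sigma[0] < 1.8  # sanity: near 1.64

    def test_all_equal_distances_flagged_unattainable(self):
        d = np.full((1, 4), 2.5)
        _, sigma, flags = local_scales(d, k=4)
        assert flags[0]
        assert sigma[0] == pytest.approx(0.5 * (1e-6 + 1e3))

    def test_nearest_neighbor_weight_is_one(self):
        X = np.array([[0.0], [0.5], [1.5], [2.5]])
        nbrs, d = knn_distances(X, k=3)
        rho, sigma, _ = local_scales(d, k=3)
        W = membership_strengths(d, nbrs, rho, sigma, normalize=False)
        assert W[0, nbrs[0, 0]] == pytest.approx(1.0)  # d == rho -> e^0


class TestMembershipAndSymmetrization:
    def test_monotone_in_distance(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        nbrs, d = knn_distances(X, k=3)
        rho, sigma, _ = local_scales(d, k=3)
        W = membership_strengths(d, nbrs, rho, sigma, normalize=False)
        assert W[0, 1] > W[0, 2] > W[0, 3] > 0

    def test_row_normalization_contract(self, rng):
        X = rng.standard_normal((30, 4))
        nbrs, d = knn_distances(X, 5)
        rho, sigma, _ = local_scales(d, 5)
        W = membership_strengths(d, nbrs, rho, sigma, normalize=True)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("wij,wji,expected", [
        (1.0, 0.0, 1.0), (0.5, 0.5, 0.75), (0.0, 0.0, 0.0),
    ])
    def test_symmetrize_formula(self, wij, wji, expected):
        W = np.array([[0.0, wij], [wji, 0.0]])
        P = symmetrize(W)
        assert P[0, 1] == pytest.approx(expected)
        assert P[1, 0] == P[0, 1]

    def test_fuzzy_graph_invariants(self, rng):
        X = rng.standard_normal((40, 6))
        g = fuzzy_graph(X, k=8)
        assert np.allclose(g.P, g.P.T)
        assert g.P.min() >= 0 and g.P.max() <= 1
        assert np.all(np.diag(g.P) == 0)
        assert np.all(g.rho >= 0) and np.all(g.sigma > 0)


class TestLowDimSimilarityAndLoss:
    @pytest.mark.parametrize("dist,expected", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.1)])
    def test_kernel_values(self, dist, expected):
        assert low_dim_similarity([0.0, 0.0], [dist, 0.0]) == pytest.approx(expected)

    def test_zero_loss_at_matching_distributions(self):
        # two points at distance r have q = p when p is set to (1+r^2)^-1
        Y = np.array([[0.0, 0.0], [1.0, 0.0]])
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert cross_entropy(P, Y) == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_log2_contribution(self):
        # p=1, q=0.5: contribution log 2 per ordered pair
        Y = np.array([[0.0, 0.0], [1.0, 0.0]])
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert cross_entropy(P, Y) == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_loss_decreases_toward_target(self):
        P = np.array([[0.0, 0.8], [0.8, 0.0]])
        losses = [cross_entropy(P, np.array([[0.0, 0.0], [d, 0.0]]))
                  for d in (2.0, 1.0, 0.5)]  # q -> p as d shrinks to 0.5
        assert losses[0] > losses[1] > losses[2]

    def test_loss_nonnegative(self, rng):
        X = rng.standard_normal((20, 3))
        g = fuzzy_graph(X, 5)
        Y = rng.standard_normal((20, 2))
        assert cross_entropy(g.P, Y) >= 0


class TestOptimizeEmbedding:
    def test_stationary_at_matching_q(self):
        # n=2 with p = q: the full-pairs gradient is exactly zero
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        Y0 = np.array([[0.0, 0.0], [1.0, 0.0]])  # distance 1 -> q = 0.5 = p
        cfg = UmapConfig(n_neighbors=2, n_epochs=5, negative_samples=0,
                         learning_rate=0.1)
        Y = optimize_embedding(P, cfg, initial_layout=Y0)
        assert np.array_equal(Y, Y0)

    def test_full_gradient_descends_loss(self, rng):
        """Full-pairs mode at small learning rate: loss non-increasing."""
        X = rng.standard_normal((30, 4))
        g = fuzzy_graph(X, 5)
        cfg = UmapConfig(n_neighbors=5, n_epochs=60, negative_samples=0,
                         learning_rate=0.05, seed=1)
        _, losses = optimize_embedding(g.P, cfg, X=X, return_loss=True)
        assert np.all(np.diff(losses) <= 1e-9)

    def test_blob_separation_end_to_end(self):
        """Two tight blobs, inter/intra ratio 10: stays separated, 5/5 seeds."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = np.vstack([r.normal(0, 1, (20, 4)), r.normal(10, 1, (20, 4))])
            Y = umap_embed(X, UmapConfig(n_neighbors=5, seed=seed, n_epochs=150))
            within = np.mean([np.linalg.norm(Y[:20] - Y[:20].mean(0), axis=1).mean(),
                              np.linalg.norm(Y[20:] - Y[20:].mean(0), axis=1).mean()])
            between = np.linalg.norm(Y[:20].mean(0) - Y[20:].mean(0))
            assert between / within > 3

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((40, 5))
        cfg = UmapConfig(n_neighbors=6, n_epochs=50, seed=7)
        assert np.array_equal(umap_embed(X, cfg), umap_embed(X, cfg))

    def test_three_point_toy_near_grid_search_optimum(self):
        """Full-pairs descent at small eta stays within 1e-3 of the grid oracle."""
        P = np.array([[0.0, 0.9, 0.1],
                      [0.9, 0.0, 0.1],
                      [0.1, 0.1, 0.0]])
        # oracle: exhaustive 1-D layouts (y0 = 0 wlog)
        grid = np.linspace(-6, 6, 241)
        oracle_loss, oracle_ab = min(
            (cross_entropy(P, np.array([[0.0], [a], [b]])), (a, b))
            for a in grid for b in grid
        )
        cfg = UmapConfig(n_neighbors=2, n_epochs=500, negative_samples=0,
                         learning_rate=0.02, n_components=1)
        Y = optimize_embedding(
            P, cfg,
            initial_layout=np.array([[0.0], [oracle_ab[0]], [oracle_ab[1]]]))
        assert cross_entropy(P, Y) <= oracle_loss + 1e-3


class TestUmapEmbedPipeline:
    def test_trivial_two_cluster_recovery(self):
        r = np.random.default_rng(3)
        X = np.vstack([r.normal(0, 0.2, (5, 3)), r.normal(8, 0.2, (5, 3))])
        Y = umap_embed(X, UmapConfig(n_neighbors=3, seed=0, n_epochs=150))
        from sklearn.cluster import KMeans
        labels = KMeans(2, n_init=10, random_state=0).fit_predict(Y)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_permutation_equivariance_full_pairs(self, rng):
        X = rng.standard_normal((20, 4))
        perm = rng.permutation(20)
        cfg = UmapConfig(n_neighbors=4, n_epochs=40, negative_samples=0, seed=0)
        Y = umap_embed(X, cfg)
        Yp = umap_embed(X[perm], cfg)
        assert np.allclose(Yp, Y[perm], atol=1e-8)

    def test_output_shape(self, rng):
        X = rng.standard_normal((25, 6))
        Y = umap_embed(X, UmapConfig(n_neighbors=4, n_epochs=20))
        assert Y.shape == (25, 2)

    def test_neighbor_clamp_on_small_input(self, rng):
        X = rng.standard_normal((20, 3))
        Y = umap_embed(X, UmapConfig(n_neighbors=150, n_epochs=10))
        assert Y.shape == (20, 2)

    def test_pca_init_requires_features(self, rng):
        X = rng.standard_normal((15, 3))
        g = fuzzy_graph(X, 4)
        with pytest.raises(ValueError, match="PCA init"):
            optimize_embedding(g.P, UmapConfig(n_neighbors=4, n_epochs=5))
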