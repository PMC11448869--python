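"""Operator construction vs dense oracle, imputation, spectra, clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from clonofate.diffusion import (
    DiffusionOperator,
    GraphParams,
    cluster_cells,
    diffusion_distance,
    pca_reduce,
)
from clonofate.core import ConfigError


def dense_operator(X, k, ka):
    """Brute-force dense construction of K and P (the independent oracle)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    K = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        neighbors = [j for j in order if j != i][:k]
        sigma = D[i, neighbors[ka - 1]]
        for j in neighbors:
            K[i, j] = np.exp(-((D[i, j] / sigma) ** 2))
    K = (K + K.T) / 2 + np.eye(n)
    P = K / K.sum(axis=1, keepdims=True)
    return K, P


class TestOperatorConstruction:
    def test_three_collinear_points_by_hand(self):
        """Equally spaced collinear points, k=2, ka=1: the 3x3 operator is
        hand-computable.  sigma_i = 1 for all; K has exp(-1) between
        adjacent points and exp(-4) between the endpoints (already
        symmetric), plus the unit diagonal."""
        X = np.array([[0.0], [1.0], [2.0]])
        op = DiffusionOperator(k=2, ka=1, t=1).fit(X)
        e1, e4 = np.exp(-1.0), np.exp(-4.0)
        K_expected = np.array(
            [[1.0, e1, e4], [e1, 1.0, e1], [e4, e1, 1.0]]
        )
        P_expected = K_expected / K_expected.sum(axis=1, keepdims=True)
        assert np.allclose(op.K_.toarray(), K_expected)
        assert np.allclose(op.P_.toarray(), P_expected)

    @pytest.mark.parametrize("n,k,ka", [(20, 5, 2), (50, 10, 4), (35, 30, 10)])
    def test_sparse_pipeline_equals_dense_oracle(self, rng, n, k, ka):
        X = rng.normal(size=(n, 3))
        op = DiffusionOperator(k=k, ka=ka, t=3).fit(X)
        K, P = dense_operator(X, k, ka)
        assert np.abs(op.K_.toarray() - K).max() < 1e-8
        assert np.abs(op.P_.toarray() - P).max() < 1e-8
        Y = rng.normal(size=(n, 4))
        assert np.abs(op.transform(Y) - P @ P @ P @ Y).max() < 1e-8

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(120, 5))
        op = DiffusionOperator(k=15, ka=5).fit(X)
        sums = np.asarray(op.P_.sum(axis=1)).ravel()
        assert np.abs(sums - 1).max() < 1e-10

    def test_separated_clusters_near_block_diagonal(self, rng):
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2)) + 1000.0
        op = DiffusionOperator(k=5, ka=2).fit(np.vstack([a, b]))
        P = op.P_.toarray()
        off = max(P[:30, 30:].max(initial=0.0), P[30:, :30].max(initial=0.0))
        assert off < 1e-6

    def test_duplicate_points_sigma_fallback_warns(self, rng):
        X = rng.normal(size=(20, 2))
        X[1] = X[0]  # exact duplicate → sigma would be 0 at ka=1
        with pytest.warns(UserWarning, match="sigma=0"):
            op = DiffusionOperator(k=3, ka=1).fit(X)
        assert (op.sigmas_ > 0).all()

    def test_identical_points_error(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="identical"):
            DiffusionOperator(k=3, ka=1).fit(X)

    def test_too_few_cells_error(self, rng):
        with pytest.raises(ValueError, match="k\\+1"):
            DiffusionOperator(k=30, ka=10).fit(rng.normal(size=(10, 2)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            GraphParams(k=10, ka=11)
        with pytest.raises(ConfigError):
            GraphParams(t=-1)


class TestImputation:
    def test_t_zero_is_identity(self, rng):
        X = rng.normal(size=(40, 3))
        op = DiffusionOperator(k=5, ka=2).fit(X)
        Y = rng.normal(size=(40, 6))
        assert np.array_equal(op.transform(Y, t=0), Y)

    def test_constant_column_invariant(self, rng):
        X = rng.normal(size=(40, 3))
        op = DiffusionOperator(k=5, ka=2).fit(X)
        const = np.full((40, 1), 3.7)
        for t in (1, 4, 20):
            assert np.allclose(op.transform(const, t=t), 3.7)

    def test_long_time_limit_is_stationary_mean(self, rng):
        X = rng.normal(size=(30, 2))
        op = DiffusionOperator(k=6, ka=2).fit(X)
        n_comp, _ = op.connected_components()
        assert n_comp == 1
        Y = rng.normal(size=(30, 3))
        pi = op.degrees_ / op.degrees_.sum()
        limit = pi @ Y
        out = op.transform(Y, t=1000)
        assert np.abs(out - limit[None, :]).max() < 1e-6

    def test_linearity(self, rng):
        X = rng.normal(size=(40, 3))
        op = DiffusionOperator(k=5, ka=2).fit(X)
        A, B = rng.normal(size=(40, 2)), rng.normal(size=(40, 2))
        lhs = op.transform(2.0 * A - 3.0 * B)
        rhs = 2.0 * op.transform(A) - 3.0 * op.transform(B)
        assert np.allclose(lhs, rhs)

    def test_negative_t_error(self, rng):
        op = DiffusionOperator(k=3, ka=1).fit(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            op.transform(np.zeros((10, 1)), t=-1)


class TestDiffusionMap:
    def test_chain_eigenvalues_match_dense_eigensolver(self, rng):
        X = np.linspace(0, 1, 12)[:, None] + rng.normal(0, 1e-3, size=(12, 1))
        op = DiffusionOperator(k=3, ka=1).fit(X)
        dmap = op.diffusion_map(n_dcs=5)
        # oracle: dense nonsymmetric eigendecomposition of P itself
        evals = np.linalg.eigvals(op.P_.toarray())
        evals = np.sort(evals.real)[::-1]
        assert np.allclose(dmap.eigenvalues, evals[1 : 1 + dmap.n_dcs], atol=1e-8)

    def test_trivial_eigenvalue_dropped_and_rest_below_one(self, rng):
        op = DiffusionOperator(k=5, ka=2).fit(rng.normal(size=(40, 3)))
        dmap = op.diffusion_map(n_dcs=6)
        assert (dmap.eigenvalues < 1 - 1e-10).all()
        assert (dmap.eigenvalues > 0).all()

    def test_components_orthonormal_under_stationary_inner_product(self, rng):
        op = DiffusionOperator(k=5, ka=2).fit(rng.normal(size=(40, 3)))
        dmap = op.diffusion_map(n_dcs=5)
        pi = op.degrees_ / op.degrees_.sum()
        gram = dmap.components.T @ (pi[:, None] * dmap.components)
        assert np.abs(gram - np.eye(dmap.n_dcs)).max() < 1e-8

    def test_disconnected_graph_yields_per_component_maps(self, rng):
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) + 1e6
        op = DiffusionOperator(k=4, ka=2).fit(np.vstack([a, b]))
        # distant blocks: kernel affinities across are exactly 0 only in the
        # kNN sense; assert components reported
        n_comp, labels = op.connected_components()
        if n_comp > 1:
            with pytest.warns(UserWarning, match="components"):
                dmap = op.diffusion_map(n_dcs=3)
            assert dmap.component_labels is not None


class TestDiffusionDistance:
    def test_identical_cells_distance_zero(self, rng):
        X = rng.normal(size=(30, 2))
        X[5] = X[4] + 1e-12
        op = DiffusionOperator(k=5, ka=2).fit(X)
        D = diffusion_distance(op.diffusion_map(n_dcs=4))
        assert D[4, 5] < 1e-6

    def test_metric_properties(self, rng):
        op = DiffusionOperator(k=5, ka=2).fit(rng.normal(size=(25, 3)))
        D = diffusion_distance(op.diffusion_map(n_dcs=4))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        n = D.shape[0]
        for i in range(0, n, 5):
            for j in range(0, n, 5):
                for m in range(0, n, 5):
                    assert D[i, j] <= D[i, m] + D[m, j] + 1e-10

    def test_chain_geometry_orders_group_distances(self, rng):
        # clusters A-B adjacent on a line, C distal; spread keeps the
        # graph connected so diffusion distances span all three
        a = rng.normal(size=(40, 2)) * 0.8
        b = rng.normal(size=(40, 2)) * 0.8 + [3, 0]
        c = rng.normal(size=(40, 2)) * 0.8 + [6, 0]
        X = np.vstack([a, b, c])
        labels = np.repeat(["A", "B", "C"], 40)
        op = DiffusionOperator(k=15, ka=5).fit(X)
        assert op.connected_components()[0] == 1
        D = diffusion_distance(op.diffusion_map(n_dcs=5), labels=labels)
        # group order is sorted: A=0, B=1, C=2
        assert D[0, 1] < D[0, 2]


class TestPCAReduce:
    def test_rank_one_matrix_single_direction(self, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=8))
        scores, evr = pca_reduce(X, n_pcs=4)
        assert evr[0] > 1 - 1e-10
        assert np.allclose(scores[:, 1:], 0, atol=1e-8)

    def test_reconstruction_error_equals_discarded_variance(self, rng):
        X = rng.normal(size=(50, 10))
        Xc = X - X.mean(axis=0)
        scores, _ = pca_reduce(X, n_pcs=4)
        # total variance − retained variance = sum of discarded eigenvalues
        cov_eigs = np.sort(np.linalg.eigvalsh(np.cov(Xc.T, ddof=1)))[::-1]
        retained = scores.var(axis=0, ddof=1).sum()
        assert np.isclose(cov_eigs.sum() - retained, cov_eigs[4:].sum())

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(40, 6))
        s1, _ = pca_reduce(X, n_pcs=3)
        s2, _ = pca_reduce(X.copy(), n_pcs=3)
        assert np.array_equal(s1, s2)

    def test_n_pcs_too_large_error(self, rng):
        with pytest.raises(ValueError, match="n_pcs"):
            pca_reduce(rng.normal(size=(5, 3)), n_pcs=4)


class TestClusterCells:
    def test_two_blobs_fully_recovered(self, rng):
        X = np.vstack(
            [rng.normal(size=(50, 2)), rng.normal(size=(50, 2)) + 50.0]
        )
        truth = np.repeat([0, 1], 50)
        labels = cluster_cells(X, k=30, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(80, 4))
        a = cluster_cells(X, k=10, seed=3)
        b = cluster_cells(X, k=10, seed=3)
        assert np.array_equal(a, b)

    def test_k_too_large_error(self, rng):
        with pytest.raises(ValueError, match="k="):
            cluster_cells(rng.normal(size=(10, 2)), k=10, seed=0)
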