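import numpy as np
import pytest

from panelnet.ggm import (
    CorrelationMatrix,
    EstimationConfig,
    correlation_matrix,
    ebic,
    ebic_select,
    global_strength,
    graphical_lasso,
    kkt_residual,
    lambda_path,
    precision_to_partial,
)


@pytest.fixture(scope="module")
def sample_corr():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((300, 8))
    X[:, 1] += 0.6 * X[:, 0]
    X[:, 5] += 0.5 * X[:, 4]
    return correlation_matrix(X)


class TestCorrelationMatrix:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        S = correlation_matrix(rng.standard_normal((20000, 5))).S
        off = S[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_duplicated_column_perfectly_correlated(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        S = correlation_matrix(np.column_stack([x, x, rng.standard_normal(100)])).S
        assert S[0, 1] == pytest.approx(1.0)

    def test_small_table_matches_hand_computation(self):
        # 5 rows, 3 variables; compare to the definitional formula per pair
        X = np.array([[1, 2, 1], [2, 1, 3], [3, 5, 2], [4, 4, 5], [5, 3, 4]], float)
        S = correlation_matrix(X).S
        for i in range(3):
            for j in range(3):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert S[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_column_rejected(self):
        X = np.ones((50, 3))
        X[:, 0] = np.arange(50)
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(X)

    def test_spearman_is_rank_pearson(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 4))
        S1 = correlation_matrix(X, "spearman").S
        ranks = np.argsort(np.argsort(X, axis=0), axis=0).astype(float)
        S2 = correlation_matrix(ranks, "pearson").S
        assert np.allclose(S1, S2, atol=1e-10)


class TestGraphicalLasso:
    def test_identity_input_gives_identity_precision(self):
        S = CorrelationMatrix(np.eye(4), "pearson", 100)
        for lam in (0.01, 0.3, 1.0):
            K = graphical_lasso(S, lam)
            assert np.allclose(K, np.eye(4), atol=1e-8)

    def test_full_shrinkage_beyond_lambda_max(self, sample_corr):
        lam = np.abs(sample_corr.S - np.eye(sample_corr.p)).max() * 1.001
        K = graphical_lasso(sample_corr, lam)
        assert np.count_nonzero(K - np.diag(np.diag(K))) == 0

    def test_lambda_zero_matches_direct_inversion(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 4))
        S = correlation_matrix(X)
        K = graphical_lasso(S, 0.0)
        W = precision_to_partial(K, 0.0)
        W_ref = precision_to_partial(np.linalg.inv(S.S), 0.0)
        assert np.abs(W - W_ref).max() < 1e-4

    def test_agrees_with_sklearn_solver(self, sample_corr):
        # independent reference implementation of the same objective
        from sklearn.covariance import graphical_lasso as sk_glasso
        lmax = np.abs(sample_corr.S - np.eye(sample_corr.p)).max()
        for lam in np.geomspace(0.9 * lmax, 0.02 * lmax, 8):
            K = graphical_lasso(sample_corr, float(lam))
            _, K_ref = sk_glasso(sample_corr.S, float(lam), tol=1e-6,
                                 enet_tol=1e-9, max_iter=2000)
            assert np.abs(K - K_ref).max() < 1e-4

    def test_kkt_conditions_along_path(self, sample_corr):
        cfg = EstimationConfig(n_lambda=30)
        for lam in lambda_path(sample_corr, cfg):
            K = graphical_lasso(sample_corr, float(lam), cfg)
            assert kkt_residual(sample_corr, K, float(lam)) < 1e-4

    def test_edge_count_monotone_in_penalty(self, sample_corr):
        cfg = EstimationConfig(n_lambda=40)
        counts = []
        for lam in lambda_path(sample_corr, cfg):  # decreasing lambda
            K = graphical_lasso(sample_corr, float(lam), cfg)
            W = precision_to_partial(K, cfg.edge_zero_tolerance)
            counts.append(np.count_nonzero(np.triu(W, 1)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPartialsAndStrength:
    def test_diagonal_precision_gives_empty_network(self):
        assert np.all(precision_to_partial(np.diag([1.0, 2.0, 3.0])) == 0)

    def test_two_node_formula(self):
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert precision_to_partial(K)[0, 1] == pytest.approx(0.5)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((6, 6))
        K = A @ A.T + 6 * np.eye(6)
        W = precision_to_partial(K, 0.0)
        for i in range(6):
            for j in range(6):
                expect = 0.0 if i == j else -K[i, j] / np.sqrt(K[i, i] * K[j, j])
                assert W[i, j] == pytest.approx(expect, abs=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partial(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_global_strength_brute_force(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(-0.3, 0.3, (7, 7))
        W = np.triu(W, 1)
        W = W + W.T
        expect = sum(abs(W[i, j]) for i in range(7) for j in range(i + 1, 7))
        assert global_strength(W) == pytest.approx(expect)
        assert global_strength(np.zeros((5, 5))) == 0.0


class TestEbicSelection:
    def test_gamma_zero_is_plain_bic(self, sample_corr):
        K = graphical_lasso(sample_corr, 0.05)
        E = int(np.count_nonzero(np.triu(K, 1)))
        sign, logdet = np.linalg.slogdet(K)
        ll = logdet - np.trace(sample_corr.S @ K)
        expect = -sample_corr.n * ll + E * np.log(sample_corr.n)
        assert ebic(sample_corr, K, sample_corr.n, 0.0) == pytest.approx(expect)

    def test_single_strong_edge_recovered(self):
        # truth: one partial correlation of 0.5, all else empty
        K_true = np.eye(10)
        K_true[0, 1] = K_true[1, 0] = -0.5
        Sigma = np.linalg.inv(K_true)
        hits, weights = 0, []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.multivariate_normal(np.zeros(10), Sigma, size=2000)
            net = ebic_select(correlation_matrix(X))
            off = np.triu(net.W, 1)
            if off[0, 1] != 0:
                hits += 1
                weights.append(off[0, 1])
            assert np.count_nonzero(off) - (off[0, 1] != 0) <= 1  # few spurious edges
        assert hits == 10
        assert abs(np.mean(weights) - 0.5) < 0.1

    def test_ties_resolve_to_sparser_network(self):
        # identity correlation: every lambda gives the empty network and the
        # same EBIC; the largest penalty must be selected
        S = CorrelationMatrix(np.eye(5), "pearson", 500)
        rng_S = S.S.copy()
        rng_S[0, 1] = rng_S[1, 0] = 0.02  # tiny off-diagonal to define a path
        S = CorrelationMatrix(rng_S, "pearson", 500)
        net = ebic_select(S, EstimationConfig(n_lambda=20))
        assert net.n_edges == 0
        assert net.selected_lambda == pytest.approx(net.lambda_path[0])
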