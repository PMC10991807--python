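import numpy as np
import pandas as pd
import pytest

from panelnet.ggm import EstimationConfig
from panelnet.resample import (
    StabilityResult,
    case_dropping,
    cs_coefficient,
    edge_bootstrap,
    nct,
)

FAST = EstimationConfig(n_lambda=25)


def gg_sample(rng, n, K=None, p=10):
    if K is None:
        K = np.eye(p)
    Sigma = np.linalg.inv(K)
    return rng.multivariate_normal(np.zeros(p), Sigma, size=n)


class TestNCT:
    def test_identical_samples_are_indistinguishable(self):
        rng = np.random.default_rng(0)
        X = gg_sample(rng, 300)
        res = nct(X, X.copy(), n_perm=100, paired=True, seed=1, est_cfg=FAST)
        assert res.M_obs == 0 and res.S_obs == 0
        assert res.p_M == 1.0 and res.p_S == 1.0

    def test_p_values_never_zero(self):
        # strong genuine difference: p bounded below by 1/(n_perm+1)
        rng = np.random.default_rng(1)
        K = np.eye(10)
        K[0, 1] = K[1, 0] = -0.45
        Xa = gg_sample(rng, 500, K)
        Xb = gg_sample(rng, 500)
        res = nct(Xa, Xb, n_perm=100, paired=False, seed=2, est_cfg=FAST)
        assert res.p_M >= 1 / 101
        assert res.p_M < 0.05

    def test_power_against_single_edge_difference(self):
        K = np.eye(10)
        K[0, 1] = K[1, 0] = -0.4
        hits = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            Xa = gg_sample(rng, 500, K)
            Xb = gg_sample(rng, 500)
            res = nct(Xa, Xb, n_perm=99, paired=False, seed=seed, est_cfg=FAST)
            hits += res.p_M < 0.05
        assert hits >= 0.8 * reps

    @pytest.mark.filterwarnings("ignore:n_perm")
    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        Xa = gg_sample(rng, 200)
        Xb = gg_sample(rng, 200)
        perm = np.random.default_rng(0).permutation(10)
        r1 = nct(Xa, Xb, n_perm=60, paired=True, seed=5, est_cfg=FAST)
        r2 = nct(Xa[:, perm], Xb[:, perm], n_perm=60, paired=True, seed=5, est_cfg=FAST)
        assert r1.p_M == r2.p_M and r1.p_S == r2.p_S
        assert r1.M_obs == pytest.approx(r2.M_obs, abs=1e-10)

    @pytest.mark.filterwarnings("ignore:n_perm")
    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(4)
        Xa = gg_sample(rng, 200)
        Xb = gg_sample(rng, 200)
        r1 = nct(Xa, Xb, n_perm=50, paired=True, seed=9, est_cfg=FAST)
        r2 = nct(Xa, Xb, n_perm=50, paired=True, seed=9, est_cfg=FAST)
        assert np.array_equal(r1.perm_M, r2.perm_M)
        assert r1.p_M == r2.p_M

    def test_short_permutation_runs_warn(self):
        rng = np.random.default_rng(5)
        X = gg_sample(rng, 100, p=4)
        with pytest.warns(UserWarning, match="coarse"):
            nct(X, X, n_perm=20, paired=True, seed=0, est_cfg=FAST)


class TestEdgeBootstrap:
    def test_ci_width_shrinks_with_n(self):
        K = np.eye(6)
        K[0, 1] = K[1, 0] = -0.4
        K[2, 3] = K[3, 2] = -0.3
        widths = []
        for n in (300, 3000):
            rng = np.random.default_rng(6)
            X = rng.multivariate_normal(np.zeros(6), np.linalg.inv(K), size=n)
            br = edge_bootstrap(X, n_boot=200, seed=7, est_cfg=FAST)
            widths.append((br.edge_ci_upper - br.edge_ci_lower).mean())
        assert widths[1] < widths[0]

    def test_true_zero_edges_covered(self):
        # in a null network, the vast majority of 95% CIs must contain zero
        rng = np.random.default_rng(8)
        X = gg_sample(rng, 500, p=6)
        br = edge_bootstrap(X, n_boot=200, seed=9, est_cfg=FAST)
        covered = (br.edge_ci_lower <= 0) & (0 <= br.edge_ci_upper)
        assert covered.mean() >= 0.9

    def test_estimates_inside_their_cis(self):
        rng = np.random.default_rng(10)
        K = np.eye(6)
        K[0, 1] = K[1, 0] = -0.4
        X = rng.multivariate_normal(np.zeros(6), np.linalg.inv(K), size=800)
        br = edge_bootstrap(X, n_boot=300, seed=11, est_cfg=FAST)
        inside = (br.edge_ci_lower <= br.edge_estimates) & (br.edge_estimates <= br.edge_ci_upper)
        assert inside.mean() >= 0.95

    def test_rejects_tiny_bootstrap_counts(self):
        with pytest.raises(ValueError, match="n_boot"):
            edge_bootstrap(np.zeros((10, 3)), n_boot=50)


class TestCaseDropping:
    def test_small_drop_keeps_high_correlation(self):
        # strong, well-separated structure: EI ordering survives subsampling
        K = np.eye(8)
        for i in range(3):
            K[i, i + 1] = K[i + 1, i] = -0.35
        rng = np.random.default_rng(12)
        X = rng.multivariate_normal(np.zeros(8), np.linalg.inv(K), size=2000)
        from panelnet.centrality import expected_influence
        from panelnet.ggm import correlation_matrix, ebic_select

        def stat(V):
            return expected_influence(ebic_select(correlation_matrix(V), FAST))

        stab = case_dropping(X, stat, drop_grid=(0.1, 0.4, 0.7), n_boot=30, seed=13)
        med = stab.table.groupby("proportion")["correlation"].median()
        assert (med >= 0.7).all()

    def test_tuple_values_subsampled_jointly(self):
        rng = np.random.default_rng(14)
        w1 = rng.standard_normal((400, 5))
        w2 = w1 * 0.5 + rng.standard_normal((400, 5))

        def stat(pair):
            a, b = pair
            # per-node lag-1 correlation; requires aligned rows
            return np.array([np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(5)])

        stab = case_dropping((w1, w2), stat, drop_grid=(0.2,), n_boot=20, seed=15)
        assert (stab.table["correlation"] > 0.5).mean() > 0.9

    def test_dict_statistics_tracked_separately(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((300, 4))

        def stat(V):
            return {"mean": V.mean(axis=0), "sd": V.std(axis=0)}

        stab = case_dropping(X, stat, drop_grid=(0.25,), n_boot=10, seed=17)
        assert set(stab.table["statistic"]) == {"mean", "sd"}

    def test_infeasible_proportion_skipped_with_warning(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((30, 5))
        with pytest.warns(UserWarning, match="skipped"):
            stab = case_dropping(X, lambda V: V.mean(axis=0),
                                 drop_grid=(0.2, 0.9), n_boot=5, seed=19)
        assert set(stab.table["proportion"]) == {0.2}


class TestCSCoefficient:
    def _stab(self, rows):
        table = pd.DataFrame(rows, columns=["statistic", "proportion", "replicate", "correlation"])
        return StabilityResult(table=table, drop_grid=(0.1, 0.3, 0.5, 0.75), n_boot=20)

    def test_perfect_correlations_give_max_grid(self):
        rows = [("s", p, b, 1.0) for p in (0.1, 0.3, 0.5, 0.75) for b in range(20)]
        assert cs_coefficient(self._stab(rows)) == 0.75

    def test_degradation_at_smallest_proportion_gives_zero(self):
        # 10% of correlations below 0.7 already at the first grid point
        rows = [("s", p, b, 0.5 if b < 2 else 0.9)
                for p in (0.1, 0.3, 0.5, 0.75) for b in range(20)]
        assert cs_coefficient(self._stab(rows)) == 0.0

    def test_known_crossing_point(self):
        # >= 95% of correlations above 0.7 at 0.1 and 0.3; below at 0.5+
        def corr(p, b):
            if p <= 0.3:
                return 0.95
            return 0.6 if b < 5 else 0.9
        rows = [("s", p, b, corr(p, b)) for p in (0.1, 0.3, 0.5, 0.75) for b in range(20)]
        assert cs_coefficient(self._stab(rows)) == 0.3

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs_coefficient(self._stab([]))

    def test_statistic_must_be_named_when_ambiguous(self):
        rows = [(s, 0.1, b, 1.0) for s in ("a", "b") for b in range(3)]
        stab = self._stab(rows)
        with pytest.raises(ValueError, match="pick one"):
            cs_coefficient(stab)
        assert cs_coefficient(stab, "a") == 0.1
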