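import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonpairs import assoc_stats as st


def tau_oracle(x, y):
    """Sign-covariance Kendall tau by direct O(n^2) enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cxy = cxx = cyy = 0.0
    n = len(x)
    for k in range(n):
        for l in range(n):
            sx = np.sign(x[k] - x[l])
            sy = np.sign(y[k] - y[l])
            cxy += sx * sy
            cxx += sx * sx
            cyy += sy * sy
    return cxy / np.sqrt(cxx * cyy)


class TestMarginalSpearman:
    def test_monotone_identity_and_reversal(self):
        assert st.spearman_corr([1, 2, 3], [10, 20, 30]).coefficient == 1.0
        assert st.spearman_corr([1, 2, 3], [3, 2, 1]).coefficient == -1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.random(40)
        y = rng.random(40)
        base = st.spearman_corr(x, y).coefficient
        assert st.spearman_corr(np.exp(5 * x), y).coefficient == pytest.approx(base)
        assert st.spearman_corr(x, y ** 3).coefficient == pytest.approx(base)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, 60).astype(float)
        y = rng.random(60)
        res = st.spearman_corr(x, y)
        sp = stats.spearmanr(x, y)
        assert res.coefficient == pytest.approx(sp.statistic, abs=1e-12)
        assert res.analytic_p == pytest.approx(sp.pvalue, rel=1e-6)

    def test_constant_input_gives_missing_coefficient(self, caplog):
        with caplog.at_level("WARNING", logger="codonpairs"):
            res = st.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.coefficient)


class TestMarginalKendall:
    def test_full_concordance(self):
        res = st.kendall_corr([1, 2, 3], [1, 2, 3])
        assert res.coefficient == 1.0

    def test_sign_zero_for_tied_pairs(self):
        # tied x pair contributes zero terms: denominator shrinks
        C = st.covariance_matrix(
            np.column_stack([[1.0, 1.0, 2.0], [1.0, 2.0, 3.0]]), "kendall"
        ).matrix
        assert C[0, 0] == 4.0  # 2 unordered non-tied pairs, counted twice
        assert C[1, 1] == 6.0

    def test_diagonal_is_n_times_n_minus_1_for_distinct_values(self):
        rng = np.random.default_rng(3)
        x = rng.permutation(25).astype(float)
        C = st.covariance_matrix(x[:, None], "kendall").matrix
        assert C[0, 0] == 25 * 24

    def test_matches_enumeration_oracle_all_permutations(self):
        """Sign-covariance tau equals O(n^2) enumeration for all n<=6 permutations."""
        for n in (3, 4, 5, 6):
            x = np.arange(n, dtype=float)
            for perm in itertools.permutations(range(n)):
                y = np.array(perm, dtype=float)
                res = st.kendall_corr(x, y)
                assert res.coefficient == pytest.approx(tau_oracle(x, y), abs=1e-12)

    def test_matches_scipy_tau_b_under_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 4, 80).astype(float)
        y = rng.integers(0, 6, 80).astype(float)
        res = st.kendall_corr(x, y)
        assert res.coefficient == pytest.approx(stats.kendalltau(x, y).statistic, abs=1e-12)


class TestCovarianceMatrix:
    def test_single_column_is_rank_variance(self):
        x = np.array([3.0, 1.0, 2.0, 4.0])
        C = st.covariance_matrix(x[:, None], "spearman").matrix
        ranks = stats.rankdata(x)
        assert C[0, 0] == pytest.approx(np.mean((ranks - ranks.mean()) ** 2))

    def test_duplicated_column_flagged_singular(self):
        rng = np.random.default_rng(5)
        x = rng.random(20)
        X = np.column_stack([x, x, rng.random(20)])
        model = st.covariance_matrix(X, "spearman", names=("a", "a_copy", "b"))
        with pytest.raises(st.SingularCovarianceError, match="a"):
            _ = model.inverse

    def test_insufficient_observations(self):
        with pytest.raises(ValueError, match="insufficient"):
            st.covariance_matrix(np.zeros((3, 3)), "spearman")

    def test_inverse_is_inverse(self):
        rng = np.random.default_rng(6)
        X = rng.random((50, 4))
        for method in st.METHODS:
            model = st.covariance_matrix(X, method)
            assert np.allclose(model.inverse @ model.matrix, np.eye(4), atol=1e-8)


class TestPartialCorrelation:
    @pytest.mark.parametrize("method", st.METHODS)
    def test_reduces_to_marginal_with_no_covariates(self, method):
        rng = np.random.default_rng(7)
        X = rng.random((40, 2))
        marginal = st._marginal(X[:, 0], X[:, 1], method, "x", "y").coefficient
        partial = st.partial_correlation(X, 0, 1, method).coefficient
        assert abs(partial - marginal) < 1e-12

    def test_single_covariate_matches_recursion_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            X = rng.random((30, 3))
            r = st.partial_correlation(X, 0, 1, "spearman").coefficient
            r01 = stats.spearmanr(X[:, 0], X[:, 1]).statistic
            r02 = stats.spearmanr(X[:, 0], X[:, 2]).statistic
            r12 = stats.spearmanr(X[:, 1], X[:, 2]).statistic
            oracle = (r01 - r02 * r12) / np.sqrt((1 - r02 ** 2) * (1 - r12 ** 2))
            assert r == pytest.approx(oracle, abs=1e-10)

    def test_exactly_collinear_covariate_raises(self):
        rng = np.random.default_rng(9)
        z = rng.random(30)
        X = np.column_stack([rng.random(30), z, z])
        with pytest.raises(st.SingularCovarianceError):
            st.partial_correlation(X, 0, 1, "spearman")

    def test_invariant_under_monotone_transform_of_covariate(self):
        rng = np.random.default_rng(10)
        X = rng.random((60, 4))
        base = st.partial_correlation(X, 0, 1, "spearman").coefficient
        X2 = X.copy()
        X2[:, 2] = np.exp(3 * X2[:, 2])
        assert st.partial_correlation(X2, 0, 1, "spearman").coefficient == pytest.approx(base)

    def test_removes_a_common_driver(self):
        # x and y both driven by z only: partial given z is near zero
        rng = np.random.default_rng(11)
        z = rng.standard_normal(4000)
        x = z + rng.standard_normal(4000)
        y = z + rng.standard_normal(4000)
        X = np.column_stack([x, y, z])
        marginal = st.partial_correlation(X[:, :2], 0, 1, "spearman").coefficient
        partial = st.partial_correlation(X, 0, 1, "spearman").coefficient
        assert marginal > 0.3
        assert abs(partial) < 0.08


class TestPermutation:
    def make_data(self, n=30, rho=0.9, seed=12):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        return np.column_stack([x, y])

    @pytest.mark.parametrize("method", st.METHODS)
    def test_deterministic_for_fixed_seed(self, method):
        X = self.make_data()
        cfg = st.PermutationConfig(n_permutations=200, seed=42)
        assert st.permutation_p(X, 0, 1, method, cfg) == st.permutation_p(X, 0, 1, method, cfg)

    def test_bounds(self):
        X = self.make_data(rho=0.0, seed=13)
        cfg = st.PermutationConfig(n_permutations=99, seed=0)
        p = st.permutation_p(X, 0, 1, "spearman", cfg)
        assert 1 / 100 <= p <= 1.0

    def test_strong_effect_hits_floor(self):
        X = self.make_data(n=100, rho=0.95)
        cfg = st.PermutationConfig(n_permutations=500, seed=1)
        assert st.permutation_p(X, 0, 1, "spearman", cfg) == 1 / 501

    def test_null_p_values_uniform(self):
        """Kolmogorov-Smirnov check on permutation P under independence."""
        rng = np.random.default_rng(14)
        pvals = []
        for rep in range(300):
            X = rng.standard_normal((25, 2))
            cfg = st.PermutationConfig(n_permutations=99, seed=int(rep))
            pvals.append(st.permutation_p(X, 0, 1, "spearman", cfg))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_one_sided_tails_are_complementary_in_count(self):
        X = self.make_data(rho=0.5, seed=15)
        n_perm = 200
        g = st.permutation_p(X, 0, 1, "spearman",
                             st.PermutationConfig(n_perm, 3, "greater"))
        l = st.permutation_p(X, 0, 1, "spearman",
                             st.PermutationConfig(n_perm, 3, "less"))
        # every permutation is counted by at least one tail (ties by both)
        assert g + l >= (n_perm + 2) / (n_perm + 1)


class TestAssociate:
    def test_listwise_deletion_varies_n(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({
            "x": rng.random(50), "y": rng.random(50), "z": rng.random(50),
        })
        df.loc[:9, "z"] = np.nan
        marginal = st.associate(df, "x", "y")
        partial = st.associate(df, "x", "y", ("z",))
        assert marginal.n == 50 and partial.n == 40

    def test_constant_predictor_returns_missing(self, caplog):
        df = pd.DataFrame({"x": np.ones(20), "y": np.arange(20.0)})
        with caplog.at_level("WARNING", logger="codonpairs"):
            res = st.associate(df, "x", "y")
        assert np.isnan(res.coefficient) and res.permutation_p is None

    def test_child_seed_independent_of_run_order(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"x": rng.random(30), "y": rng.random(30)})
        cfg = st.PermutationConfig(n_permutations=99)
        a1 = st.associate(df, "x", "y", (), "spearman", cfg, master_seed=5)
        _ = st.associate(df, "y", "x", (), "spearman", cfg, master_seed=5)
        a2 = st.associate(df, "x", "y", (), "spearman", cfg, master_seed=5)
        assert a1.permutation_p == a2.permutation_p


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        assert st.wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], "greater") == pytest.approx(0.05)

    def test_identical_groups_near_one(self):
        p = st.wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4], "two_sided")
        assert p > 0.9

    def test_antisymmetry(self):
        rng = np.random.default_rng(18)
        a, b = rng.random(12), rng.random(15)
        assert st.wilcoxon_rank_sum(a, b, "greater") == pytest.approx(
            st.wilcoxon_rank_sum(b, a, "less")
        )
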