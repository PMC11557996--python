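"""The GLS engine: fixed-lambda fits, joint lambda estimation, AICc,
likelihood R^2, slope comparisons, and univariate Brownian-motion rates."""

import numpy as np
import pytest
from scipy import stats

import carapace as cp
from carapace.gls import LAMBDA_GRID

from conftest import random_tree


def design(x):
    x = np.asarray(x, float)
    return np.column_stack([np.ones(len(x)), x])


def brute_force_gls(y, X, V):
    """Dense normal-equation oracle with explicit matrix inversion."""
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    n = len(y)
    s2 = r @ Vi @ r / n
    sign, logdet = np.linalg.slogdet(V)
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
    return beta, s2, ll


def lam_grid_oracle(y, X, M, step=1e-3):
    """Brute-force lambda grid + dense GLS, returns (best lnL, best lam)."""
    best = (-np.inf, 0.0)
    D = np.diag(np.diag(M))
    for lam in np.arange(0.0, 1.0 + step / 2, step):
        V = lam * M + (1 - lam) * D
        try:
            _, s2, ll = brute_force_gls(y, X, V)
        except np.linalg.LinAlgError:
            continue
        if np.isfinite(ll) and ll > best[0]:
            best = (ll, lam)
    return best


class TestFixedLambda:
    def test_exact_line_is_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            f = cp.gls_fit_fixed([1, 2, 3], design([0, 1, 2]), np.eye(3), 0.0)
        np.testing.assert_allclose(f.coef, [1.0, 1.0], atol=1e-12)
        assert f.sigma2 == 0.0 and f.degenerate

    def test_hand_ols(self):
        f = cp.gls_fit_fixed([1, 2, 2], design([0, 1, 2]), np.eye(3), 0.0)
        np.testing.assert_allclose(f.coef, [7 / 6, 0.5], atol=1e-12)

    def test_matches_dense_oracle_at_lambda_one(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, n_tips=6)
        M = tree.vcv().matrix
        y = rng.normal(size=6)
        X = design(rng.normal(size=6))
        f = cp.gls_fit_fixed(y, X, M, 1.0)
        beta, s2, ll = brute_force_gls(y, X, M)
        np.testing.assert_allclose(f.coef, beta, atol=1e-10)
        assert f.sigma2 == pytest.approx(s2, abs=1e-12)
        assert f.loglik == pytest.approx(ll, abs=1e-10)

    def test_error_cases(self):
        with pytest.raises(ValueError):
            cp.gls_fit_fixed([1, 2], design([0, 1]), np.eye(2), 0.0)  # n<=k
        X = np.column_stack([np.ones(4), np.ones(4)])  # singular design
        with pytest.raises(np.linalg.LinAlgError):
            cp.gls_fit_fixed([1, 2, 3, 4], X, np.eye(4), 0.0)


class TestJointLambda:
    def test_ols_equivalence_at_lambda_zero(self):
        """lambda fixed at 0 on an ultrametric tree == textbook OLS."""
        rng = np.random.default_rng(1)
        import statsmodels.api as sm

        for _ in range(5):
            tree = random_tree(rng, n_tips=25)
            M = tree.vcv().matrix
            x = rng.normal(size=25)
            y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=25)
            f = cp.gls_fit_fixed(y, design(x), M, 0.0)
            ols = sm.OLS(y, design(x)).fit()
            np.testing.assert_allclose(f.coef, ols.params, atol=1e-10)
            np.testing.assert_allclose(
                f.sigma2 * M[0, 0], ols.ssr / 25, atol=1e-10
            )

    def test_likelihood_beats_every_grid_point(self):
        rng = np.random.default_rng(2)
        tree = random_tree(rng, n_tips=40)
        C = tree.vcv()
        tab, _ = cp.simulate_allometric_dataset(
            tree, cp.SimulationConfig(n_tips=40, seed=5)
        )
        y = tab.log10_scl.to_numpy()
        X = design(tab.log10_hl)
        Co = C.subset(list(tab.species))
        f = cp.fit_pgls(y, X, Co)
        for lam in np.arange(0.0, 1.0001, 0.1):
            assert f.loglik >= cp.gls_fit_fixed(y, X, Co, lam).loglik - 1e-6

    def test_matches_fine_grid_oracle_small_trees(self):
        """fit_pgls lnL equals brute-force grid search on <=8-taxon data."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            tree = random_tree(rng, n_tips=n)
            M = tree.vcv().matrix
            x = rng.normal(size=n)
            y = 0.5 + 0.9 * x + rng.normal(scale=0.2, size=n)
            f = cp.fit_pgls(y, design(x), M)
            ll_oracle, _ = lam_grid_oracle(y, design(x), M)
            assert f.loglik >= ll_oracle - 1e-5
            assert abs(f.loglik - ll_oracle) < 1e-3

    def test_exact_line_degenerate_at_lower_bound(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning, match="degenerate"):
            f = cp.fit_pgls(2.0 + 0.75 * x, design(x), np.eye(6))
        np.testing.assert_allclose(f.coef, [2.0, 0.75], atol=1e-10)
        assert f.lam == 0.0 and f.degenerate

    def test_lambda_identifiable_at_both_ends(self, study_tree, study_vcv):
        """lambda-hat lands near the simulation truth at lambda = 0 and 1."""
        hits = {0.0: 0, 1.0: 0}
        n_rep = 25
        for s in range(1, n_rep + 1):
            for truth in (0.0, 1.0):
                tab, _ = cp.simulate_allometric_dataset(
                    study_tree,
                    cp.SimulationConfig(seed=s, lambda_resid=truth),
                )
                Co = study_vcv.subset(list(tab.species))
                f = cp.fit_pgls(
                    tab.log10_scl.to_numpy(), design(tab.log10_hl), Co
                )
                if truth == 0.0 and f.lam < 0.2:
                    hits[0.0] += 1
                if truth == 1.0 and f.lam > 0.8:
                    hits[1.0] += 1
        assert hits[0.0] >= 0.9 * n_rep
        assert hits[1.0] >= 0.9 * n_rep


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "ll,k,n,expect",
        [(0, 2, 10, 4 + 12 / 7), (-10, 2, 100, 24 + 12 / 97)],
    )
    def test_closed_form(self, ll, k, n, expect):
        assert cp.aicc(ll, k, n) == pytest.approx(expect, abs=1e-10)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            cp.aicc(0.0, 3, 4)

    def test_aic_plus_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ll = rng.normal(scale=50)
            k = int(rng.integers(1, 6))
            n = int(rng.integers(k + 2, 200))
            aic = -2 * ll + 2 * k
            assert cp.aicc(ll, k, n) - aic == pytest.approx(
                2 * k * (k + 1) / (n - k - 1), abs=1e-10
            )

    @pytest.mark.parametrize(
        "aiccs,expect",
        [
            ((0, 2), (0.7311, 0.2689)),
            ((5, 5), (0.5, 0.5)),
            ((0, 2, 4), (0.6652, 0.2447, 0.0900)),
        ],
    )
    def test_weights(self, aiccs, expect):
        np.testing.assert_allclose(cp.aicc_weights(aiccs), expect, atol=5e-5)

    def test_weights_bad_input(self):
        with pytest.raises(ValueError):
            cp.aicc_weights([0.0, np.inf])


class TestLikelihoodR2:
    def _fit_like(self, ll, n):
        f = cp.fit_ols(np.arange(n) + np.random.default_rng(0).normal(size=n),
                       design(np.arange(n)))
        f.loglik = ll
        return f

    def test_null_case_and_closed_form(self):
        a, b = self._fit_like(-5.0, 10), self._fit_like(-5.0, 10)
        assert cp.likelihood_r2(a, b) == pytest.approx(0.0, abs=1e-12)
        a.loglik = 0.0
        assert cp.likelihood_r2(a, b) == pytest.approx(1 - np.e**-1, abs=1e-10)

    def test_perfect_fit_limit(self):
        """As residual noise vanishes, the likelihood R^2 approaches 1."""
        rng = np.random.default_rng(4)
        tree = random_tree(rng, n_tips=50)
        C = tree.vcv()
        x = rng.normal(size=50)
        order = list(C.taxa)
        y = 0.6 + 0.96 * x + rng.normal(scale=1e-4, size=50)
        fit = cp.fit_pgls(y, design(x), C)
        null = cp.fit_pgls(y, np.ones((50, 1)), C)
        assert cp.likelihood_r2(fit, null) > 0.999


class TestSlopeDifference:
    def test_identical_fits(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 1 + x + rng.normal(size=30)
        f = cp.fit_ols(y, design(x), terms=["intercept", "x"])
        t, df, p = cp.slope_difference_test(f, f, "x")
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        """b=0.9 vs 1.0 with SE 0.02 each at n=201: t=-3.536, df=198."""
        n, k = 201, 2
        a = cp.FitResult(
            model="a", terms=["intercept", "x"],
            coef=np.array([0.0, 0.9]), se=np.array([0.1, 0.02]),
            tvals=np.zeros(2), pvals=np.ones(2), lam=1.0, sigma2=1.0,
            loglik=0.0, n=n, k_coef=k, k_aicc=k + 2, aicc=0.0,
            method="PGLS", lambda_estimated=True,
        )
        b = cp.FitResult(
            model="b", terms=["intercept", "x"],
            coef=np.array([0.0, 1.0]), se=np.array([0.1, 0.02]),
            tvals=np.zeros(2), pvals=np.ones(2), lam=0.0, sigma2=1.0,
            loglik=0.0, n=n, k_coef=k, k_aicc=k + 1, aicc=0.0,
            method="OLS", lambda_estimated=False,
        )
        t, df, p = cp.slope_difference_test(a, b, "x")
        assert df == 198
        assert t == pytest.approx(-0.1 / np.sqrt(2 * 0.02**2), abs=1e-6)
        assert t == pytest.approx(-3.5355, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(3.5355, 198), rel=1e-3)

    def test_missing_term_and_df_boundary(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=3)
        y = rng.normal(size=3)
        f = cp.fit_ols(y, design(x), terms=["intercept", "x"])
        with pytest.raises(ValueError, match="missing"):
            cp.slope_difference_test(f, f, "z")
        with pytest.raises(ValueError, match="df"):
            cp.slope_difference_test(f, f, "x")  # df = 3 - 2 - 1 = 0


class TestBmRate:
    def test_star_tree_closed_form(self):
        C = cp.parse_newick("(A:1,B:1,C:1);").vcv(order=["A", "B", "C"])
        r = cp.univariate_bm_rate([1, 2, 3], C, 0.0)
        assert r.root_state == pytest.approx(2.0, abs=1e-10)
        assert r.sigma2 == pytest.approx(2 / 3, abs=1e-10)

    def test_constant_trait_zero_rate(self):
        C = cp.parse_newick("(A:1,B:1,C:1);").vcv(order=["A", "B", "C"])
        assert cp.univariate_bm_rate([2, 2, 2], C, 0.0).sigma2 == 0.0

    def test_me_matches_grid_oracle(self):
        """sigma2-hat with 1% measurement error matches a (mu, s2) grid."""
        rng = np.random.default_rng(9)
        tree = random_tree(rng, n_tips=20)
        C = tree.vcv()
        M = C.matrix
        x = 2.0 + np.linalg.cholesky(0.15 * M + 1e-12 * np.eye(20)) @ \
            rng.standard_normal(20)
        r = cp.univariate_bm_rate(x, C, 0.01)
        E = np.diag((0.01 * x) ** 2)

        def negll(mu, s2):
            return -stats.multivariate_normal.logpdf(
                x, mean=np.full(20, mu), cov=s2 * M + E
            )

        s2_grid = np.linspace(max(r.sigma2 - 0.05, 1e-4), r.sigma2 + 0.05, 401)
        mu_grid = np.linspace(r.root_state - 0.3, r.root_state + 0.3, 121)
        vals = np.array([[negll(m, s) for s in s2_grid] for m in mu_grid])
        i, j = np.unravel_index(vals.argmin(), vals.shape)
        assert r.sigma2 == pytest.approx(s2_grid[j], abs=1e-4 + s2_grid[1] - s2_grid[0])
        assert -negll(r.root_state, r.sigma2) >= -vals[i, j] - 1e-8

    def test_negative_me_rejected(self):
        C = cp.parse_newick("(A:1,B:1,C:1);").vcv()
        with pytest.raises(ValueError):
            cp.univariate_bm_rate([1, 2, 3], C, -0.01)
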