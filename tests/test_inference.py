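import numpy as np
import pytest

import netdist as nd
from netdist.design import ile_block
from netdist.inference import estimate_dyadic_covariance, _ile_incidence
from netdist.pairs import PairIndex

from conftest import simulated_regression


def make_design(n_p=8, seed=0, ile=False):
    cov = nd.simulate_covariates(n_p, seed)
    table = nd.CovariateTable(
        cov, continuous=("AGE", "IQ"), categorical=("SEX", "TRT"), coi="IQ"
    )
    return nd.build_design(table, include_ile=ile), table


class TestOLS:
    def test_matches_normal_equations_oracle(self, rng):
        X, _ = make_design(8, seed=1)
        y = rng.normal(size=X.n_pairs)
        fit = nd.ols_fit(y, X)
        M = X.values
        oracle = np.linalg.inv(M.T @ M) @ M.T @ y
        assert np.allclose(fit.beta, oracle, atol=1e-10)
        # residual orthogonality
        scale = np.abs(M).max() * np.abs(y).max()
        assert np.abs(M.T @ fit.residuals).max() < 1e-6 * scale

    def test_perfect_fit_gives_zero_rss(self, rng):
        X, _ = make_design(8, seed=2)
        beta = rng.normal(size=X.n_columns)
        y = X.values @ beta
        fit = nd.ols_fit(y, X)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_intercept_only_gives_mean(self, rng):
        idx = PairIndex(5)
        X = nd.DesignMatrix(np.ones((10, 1)), ("intercept",), idx, has_intercept=True)
        y = rng.normal(size=10)
        fit = nd.ols_fit(y, X)
        assert fit.beta[0] == pytest.approx(y.mean())

    def test_rank_deficiency_names_columns(self, rng):
        idx = PairIndex(5)
        col = rng.normal(size=10)
        M = np.column_stack([np.ones(10), col, 2 * col])
        X = nd.DesignMatrix(M, ("intercept", "a", "a_twice"), idx)
        with pytest.raises(ValueError, match="a_twice"):
            nd.ols_fit(rng.normal(size=10), X)


class TestFTest:
    def test_orthogonal_noise_coi_gives_small_f(self, rng):
        X, _ = make_design(12, seed=3)
        # response built only from the confounders
        y = X.values[:, :-1] @ rng.normal(size=X.n_columns - 1)
        res = nd.f_test(y, X, "IQ")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_f_equals_squared_t_single_covariate(self, rng):
        idx = PairIndex(6)
        n = idx.n_pairs
        x = rng.normal(size=n)
        X = nd.DesignMatrix(
            np.column_stack([np.ones(n), x]), ("intercept", "x"), idx, has_intercept=True
        )
        y = 0.5 * x + rng.normal(size=n)
        res = nd.f_test(y, X, "x")
        t = res.beta["x"] / res.se["x"]
        assert res.statistic == pytest.approx(t**2)

    def test_matches_two_model_rss_oracle(self, rng):
        X, _ = make_design(10, seed=4)
        y = rng.normal(size=X.n_pairs)
        res = nd.f_test(y, X, "IQ")
        M = X.values
        k = X.columns.index("IQ")
        resid_full = y - M @ np.linalg.lstsq(M, y, rcond=None)[0]
        Mr = np.delete(M, k, axis=1)
        resid_red = y - Mr @ np.linalg.lstsq(Mr, y, rcond=None)[0]
        rss_f, rss_r = resid_full @ resid_full, resid_red @ resid_red
        df = X.n_pairs - X.n_columns
        assert res.statistic == pytest.approx((rss_r - rss_f) / (rss_f / df))

    def test_matches_statsmodels(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        X, _ = make_design(10, seed=5)
        y = rng.normal(size=X.n_pairs)
        res = nd.f_test(y, X, "IQ")
        sm_fit = statsmodels.OLS(y, X.values).fit()
        assert res.p_value == pytest.approx(sm_fit.pvalues[-1])
        assert res.statistic == pytest.approx(sm_fit.tvalues[-1] ** 2)


class TestFTestILE:
    def test_requires_ile_block(self):
        X, _ = make_design(8, seed=6)
        with pytest.raises(ValueError):
            nd.f_test_ile(np.zeros(X.n_pairs), X, "IQ")

    def test_pure_subject_effects_absorbed(self, rng):
        X, table = make_design(10, seed=7, ile=True)
        idx = X.index
        u = rng.normal(size=10)
        I, J = idx.members
        y = u[I] + u[J]
        res = nd.f_test_ile(y, X, "IQ")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_frisch_waugh_lovell_oracle(self, rng):
        X, _ = make_design(12, seed=8, ile=True)
        y = rng.normal(size=X.n_pairs)
        res = nd.f_test_ile(y, X, "IQ")
        # FWL: residualize y and the coi column on everything else
        k = X.columns.index("IQ")
        Z = np.delete(X.values, k, axis=1)
        x = X.values[:, k]
        Q, _ = np.linalg.qr(Z)
        y_r = y - Q @ (Q.T @ y)
        x_r = x - Q @ (Q.T @ x)
        df = X.n_pairs - X.n_columns
        num = (x_r @ y_r) ** 2 / (x_r @ x_r)
        f_oracle = num / ((y_r @ y_r - num) / df)
        assert res.statistic == pytest.approx(f_oracle)
        assert res.df == (1, df)

    def test_f_grows_with_injected_signal(self):
        # fixed seeded ladder of coi effect sizes on a 10-subject toy
        X, table = make_design(10, seed=9, ile=True)
        rng = np.random.default_rng(99)
        noise = rng.normal(size=X.n_pairs)
        iq_col = X.column("IQ")
        stats = []
        for amplitude in (0.0, 0.2, 0.5, 1.0):
            y = amplitude * iq_col + noise
            stats.append(nd.f_test_ile(y, X, "IQ").statistic)
        assert stats == sorted(stats)


class TestFGLS:
    def test_gamma_zero_reduces_to_f_test(self, rng):
        X, _ = make_design(10, seed=10)
        y = rng.normal(size=X.n_pairs)
        res_fgls = nd.fgls_test(y, X, "IQ", gamma=0.0)
        res_f = nd.f_test(y, X, "IQ")
        assert res_fgls.statistic == pytest.approx(res_f.statistic)
        assert res_fgls.p_value == pytest.approx(res_f.p_value)
        for c in res_f.beta:
            assert res_fgls.beta[c] == pytest.approx(res_f.beta[c])

    def test_structured_solve_matches_dense_oracle(self, rng):
        X, _ = make_design(8, seed=11)
        idx = X.index
        I, J = idx.members
        u = rng.normal(size=8)
        y = u[I] + u[J] + rng.normal(size=idx.n_pairs)
        res = nd.fgls_test(y, X, "IQ")
        # dense oracle: build Sigma explicitly and invert
        sigma2, gamma = res.extras["sigma2"], res.extras["gamma"]
        B = _ile_incidence(idx)
        S = B @ B.T - 2 * np.eye(idx.n_pairs)
        Sigma = sigma2 * np.eye(idx.n_pairs) + gamma * S
        Si = np.linalg.inv(Sigma)
        A = np.linalg.inv(X.values.T @ Si @ X.values)
        beta = A @ X.values.T @ Si @ y
        k = X.columns.index("IQ")
        f_oracle = beta[k] ** 2 / A[k, k]
        assert res.beta["IQ"] == pytest.approx(beta[k], rel=1e-8)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-8)

    def test_gamma_recovery_from_subject_effects(self):
        # residuals e_(i,j) = u_i + u_j + noise have share-one-participant
        # covariance Var(u); the moment estimator recovers it on average
        # (single-draw relative SE at n_p = 100 is ~15%, so average 30 draws)
        n_p = 100
        var_u = 0.25
        rng = np.random.default_rng(2024)
        idx = PairIndex(n_p)
        I, J = idx.members
        estimates = []
        for _ in range(30):
            u = rng.normal(0, np.sqrt(var_u), n_p)
            e = u[I] + u[J] + rng.normal(0, 0.5, idx.n_pairs)
            e = e - e.mean()
            estimates.append(estimate_dyadic_covariance(e, idx).gamma)
        assert np.mean(estimates) == pytest.approx(var_u, rel=0.10)

    def test_pd_bounds_and_clipping(self):
        idx = PairIndex(10)
        cov = nd.DyadicCovariance(sigma2=1.0, gamma=0.49, n_p=10)
        assert cov.is_pd
        assert not nd.DyadicCovariance(1.0, 0.51, 10).is_pd
        assert not nd.DyadicCovariance(1.0, -1.0 / 15, 10).is_pd

    def test_requires_intercept_design(self, rng):
        X, _ = make_design(8, seed=12, ile=True)
        with pytest.raises(ValueError):
            nd.fgls_test(rng.normal(size=X.n_pairs), X, "IQ")


class TestFreedmanLane:
    def test_p_value_bounds_and_observed_statistic(self, rng):
        X, _ = make_design(10, seed=13)
        y = rng.normal(size=X.n_pairs)
        B = 199
        res = nd.freedman_lane_test(y, X, "IQ", B, seed=5)
        assert 1 / (B + 1) <= res.p_value <= 1.0
        # the observed statistic is the ordinary partial F
        assert res.statistic == pytest.approx(nd.f_test(y, X, "IQ").statistic)

    def test_identity_relabeling_reproduces_statistic(self, rng):
        # applying the identity subject permutation to the reduced residuals
        # must reproduce F_obs exactly (the scheme's internal consistency)
        X, _ = make_design(8, seed=14)
        y = rng.normal(size=X.n_pairs)
        k = X.columns.index("IQ")
        Z = np.delete(X.values, k, axis=1)
        Q, _ = np.linalg.qr(Z)
        e = y - Q @ (Q.T @ y)
        y_star = (Q @ (Q.T @ y)) + e  # identity permutation
        res_obs = nd.f_test(y, X, "IQ")
        res_star = nd.f_test(y_star, X, "IQ")
        assert res_star.statistic == pytest.approx(res_obs.statistic)

    def test_too_few_permutations_rejected(self, rng):
        X, _ = make_design(8, seed=15)
        with pytest.raises(ValueError):
            nd.freedman_lane_test(rng.normal(size=X.n_pairs), X, "IQ", 50, seed=0)

    def test_same_seed_bit_reproducible(self, rng):
        X, _ = make_design(10, seed=16)
        y = rng.normal(size=X.n_pairs)
        r1 = nd.freedman_lane_test(y, X, "IQ", 299, seed=42)
        r2 = nd.freedman_lane_test(y, X, "IQ", 299, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_detects_strong_signal(self):
        y, table = simulated_regression(n_p=30, seed=17, signal=1.0)
        table = nd.CovariateTable(
            table.data, table.continuous, table.categorical, coi="TRT"
        )
        X = nd.build_design(table)
        res = nd.freedman_lane_test(y, X, "TRT", 499, seed=1)
        assert res.p_value <= 0.01

    def test_row_shuffle_flag_exists_but_is_not_default(self, rng):
        X, _ = make_design(10, seed=18)
        y = rng.normal(size=X.n_pairs)
        res = nd.freedman_lane_test(y, X, "IQ", 199, seed=3, permute_rows=True)
        assert res.extras["permute_rows"] is True
        res_default = nd.freedman_lane_test(y, X, "IQ", 199, seed=3)
        assert res_default.extras["permute_rows"] is False


class TestJaccardEquivalence:
    def test_jd_and_ji_give_identical_p_values(self):
        """Regressing the similarity instead of the distance flips every
        non-intercept coefficient and leaves all four tests' p-values equal."""
        cov = nd.simulate_covariates(16, 21)
        D = nd.simulate_degree_matrix(nd.layout(1, n_n=60), cov, 0.6, 22)
        keys = np.vstack([nd.key_nodes(row, 0.2).values for row in D])
        jd, _, _ = nd.condensed_values(keys, "jaccard")
        ji, _, _ = nd.condensed_values(keys, "jaccard_index")
        assert np.allclose(jd + ji, 1.0)
        table = nd.CovariateTable(
            cov, ("AGE", "IQ"), ("SEX", "TRT"), coi="TRT"
        )
        X = nd.build_design(table)
        X_ile = nd.build_design(table, include_ile=True)
        for test, design in [
            (nd.f_test, X),
            (nd.f_test_ile, X_ile),
            (nd.fgls_test, X),
        ]:
            r_jd = test(jd, design, "TRT")
            r_ji = test(ji, design, "TRT")
            assert r_jd.p_value == pytest.approx(r_ji.p_value, rel=1e-9)
            assert r_jd.beta["TRT"] == pytest.approx(-r_ji.beta["TRT"], rel=1e-9)
        p_jd = nd.freedman_lane_test(jd, X, "TRT", 299, seed=9).p_value
        p_ji = nd.freedman_lane_test(ji, X, "TRT", 299, seed=9).p_value
        assert p_jd == p_ji
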