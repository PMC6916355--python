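"""Gaussian conjugate model: standardization, posterior estimators,
marginal likelihood, empirical Bayes."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import quad

import conjugraph as cg
from conjugraph.gc_core import ALPHA_BOUNDS


class TestStandardize:
    def test_forced_values_for_three_points(self):
        # (1,2,3): centered (-1,0,1), scaled to unit mean square
        out = cg.standardize(np.array([[1.0, 5.0], [2.0, 7.0], [3.0, 4.0]]))
        r = np.sqrt(3 / 2)
        np.testing.assert_allclose(out.Y[:, 0], [-r, 0.0, r], atol=1e-12)

    def test_column_invariants_and_idempotence(self, gaussian_data):
        out = cg.standardize(gaussian_data)
        assert np.all(np.abs(out.Y.sum(axis=0)) < 1e-8)
        np.testing.assert_allclose(
            np.einsum("ij,ij->j", out.Y, out.Y) / out.n, 1.0, atol=1e-8
        )
        again = cg.standardize(out.Y, names=out.names)
        np.testing.assert_allclose(again.Y, out.Y, atol=1e-12)
        assert again.names == out.names

    def test_constant_column_is_an_error_naming_the_column(self):
        X = np.column_stack([np.full(5, 5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant column.*V1"):
            cg.standardize(X)

    def test_missing_values_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        X[:, 1] = np.arange(5.0)
        with pytest.raises(ValueError, match="missing"):
            cg.standardize(X)

    def test_dataframe_names_preserved(self, gaussian_data):
        import pandas as pd

        df = pd.DataFrame(gaussian_data, columns=[f"g{i}" for i in range(8)])
        out = cg.standardize(df)
        assert out.names == [f"g{i}" for i in range(8)]


class TestPosteriorEstimators:
    @pytest.mark.parametrize("n,p", [(40, 8), (10, 25)])
    def test_convex_combination_identity(self, rng, n, p):
        data = cg.standardize(rng.standard_normal((n, p)))
        stats = cg.sufficient_stats(data)
        hyper = cg.GCHyper.from_alpha(0.37, p, n)
        Sig = cg.posterior_covariance(stats, hyper)
        expected = hyper.alpha * np.eye(p) + (1 - hyper.alpha) * stats.S / n
        np.testing.assert_allclose(Sig, expected, atol=1e-10)

    def test_identity_fixed_point(self):
        # D=I and S=n*I: both mixture components are I
        p, n = 4, 12
        Y = np.sqrt(n) * np.eye(n)[:, :p]  # orthogonal columns of norm sqrt(n)
        stats = cg.SufficientStats(Y=Y)
        for delta in (p + 2.0, p + 10.0, p + 1000.0):
            hyper = cg.GCHyper(delta=delta, p=p, n=n)
            np.testing.assert_allclose(
                cg.posterior_covariance(stats, hyper), np.eye(p), atol=1e-10
            )
            np.testing.assert_allclose(
                cg.posterior_precision(stats, hyper),
                (delta + n) / (delta - p - 1 + n) * np.eye(p),
                atol=1e-8,
            )

    def test_limit_properties_at_extreme_delta(self, rng):
        # delta -> inf: Sigma_hat -> D, Omega_hat -> D^-1;
        # delta -> p+1: Sigma_hat -> S/n and (n>p) Omega_hat -> ((n+p+1)/n)(S/n)^-1
        n, p = 30, 6
        data = cg.standardize(rng.standard_normal((n, p)))
        stats = cg.sufficient_stats(data)
        big = cg.GCHyper(delta=p + 1 + 1e6, p=p, n=n)
        np.testing.assert_allclose(
            cg.posterior_covariance(stats, big), np.eye(p), rtol=0, atol=1e-4
        )
        np.testing.assert_allclose(
            cg.posterior_precision(stats, big), np.eye(p), rtol=0, atol=1e-4
        )
        small = cg.GCHyper(delta=p + 1 + 1e-6, p=p, n=n)
        mle = stats.S / n
        np.testing.assert_allclose(
            cg.posterior_covariance(stats, small), mle, rtol=1e-4
        )
        np.testing.assert_allclose(
            cg.posterior_precision(stats, small),
            (n + p + 1) / n * np.linalg.inv(mle),
            rtol=1e-4,
        )

    def test_positive_definite_even_when_p_exceeds_n(self, rng):
        n, p = 10, 30
        data = cg.standardize(rng.standard_normal((n, p)))
        stats = cg.sufficient_stats(data)
        hyper = cg.GCHyper.from_alpha(0.2, p, n)
        for M in (cg.posterior_covariance(stats, hyper),
                  cg.posterior_precision(stats, hyper)):
            assert np.linalg.eigvalsh(M)[0] > 0

    def test_shrinkage_vanishes_as_n_grows(self, rng):
        # with D, delta fixed the posterior mean approaches the MLE
        p = 5
        A = rng.standard_normal((p, p)) * 0.4 + np.eye(p)
        Sigma = A @ A.T
        L = np.linalg.cholesky(Sigma)
        delta = p + 5.0
        dists = []
        for n in (100, 1000, 10000):
            X = (L @ rng.standard_normal((p, n))).T
            data = cg.standardize(X)
            stats = cg.sufficient_stats(data)
            hyper = cg.GCHyper(delta=delta, p=p, n=n)
            mle = stats.S / n
            d = np.linalg.norm(cg.posterior_covariance(stats, hyper) - mle)
            dists.append(d / np.linalg.norm(mle))
        assert dists[0] > dists[1] > dists[2]


class TestInverseT:
    @pytest.mark.parametrize("n,p", [(10, 30), (30, 10)])
    def test_woodbury_matches_direct_inversion(self, rng, n, p):
        data = cg.standardize(rng.standard_normal((n, p)))
        hyper = cg.GCHyper.from_alpha(0.35, p, n)
        fast = cg.inverse_T_fast(data, hyper)
        direct = np.linalg.inv(hyper.u * np.eye(p) + data.Y.T @ data.Y)
        err = np.abs(fast - direct).max() / np.abs(direct).max()
        assert err < 1e-8

    def test_orthogonal_columns_diagonal_T(self):
        n, p = 12, 4
        Y = np.sqrt(n) * np.eye(n)[:, :p]
        data = cg.StandardizedData(Y=Y, names=list("abcd"))
        hyper = cg.GCHyper(delta=p + 2.0, p=p, n=n)  # u = 1
        np.testing.assert_allclose(
            cg.inverse_T_fast(data, hyper), np.eye(p) / (1 + n), atol=1e-10
        )

    def test_general_D_path(self, rng):
        n, p = 20, 5
        data = cg.standardize(rng.standard_normal((n, p)))
        D = np.eye(p) + 0.3
        hyper = cg.GCHyper(delta=p + 4.0, p=p, n=n, D=D)
        fast = cg.inverse_T_fast(data, hyper)
        np.testing.assert_allclose(
            fast, np.linalg.inv(hyper.F + data.Y.T @ data.Y), atol=1e-10
        )


class TestMarginalLikelihood:
    def test_univariate_quadrature_oracle(self):
        # p=1, y=(1,-1), delta=4: integrate N(y;0,s2 I) * IW1(s2;(delta-2), delta)
        y = np.array([[1.0], [-1.0]])
        stats = cg.SufficientStats(Y=y)
        delta = 4.0
        got = cg.log_marginal_likelihood(stats, cg.GCHyper(delta=delta, p=1, n=2))

        def integrand(s2):
            return np.exp(
                sps.norm.logpdf(1.0, 0, np.sqrt(s2))
                + sps.norm.logpdf(-1.0, 0, np.sqrt(s2))
            ) * sps.invgamma.pdf(s2, a=delta / 2, scale=(delta - 2) / 2)

        val, _ = quad(integrand, 0, np.inf)
        assert abs(got - np.log(val)) < 1e-6

    def test_empty_data_gives_zero(self):
        stats = cg.SufficientStats(Y=np.empty((0, 3)))
        assert cg.log_marginal_likelihood(stats, cg.GCHyper(delta=6.0, p=3, n=0)) == 0.0

    def test_column_permutation_invariance(self, rng, gaussian_data):
        data = cg.standardize(gaussian_data)
        stats = cg.sufficient_stats(data)
        hyper = cg.GCHyper(delta=data.p + 3.0, p=data.p, n=data.n)
        base = cg.log_marginal_likelihood(stats, hyper)
        perm = rng.permutation(data.p)
        stats_p = cg.SufficientStats(Y=data.Y[:, perm])
        assert abs(cg.log_marginal_likelihood(stats_p, hyper) - base) < 1e-8

    def test_general_D_matches_identity_when_D_is_identity(self, gaussian_data):
        data = cg.standardize(gaussian_data)
        stats = cg.sufficient_stats(data)
        h_fast = cg.GCHyper(delta=data.p + 3.0, p=data.p, n=data.n)
        h_dense = cg.GCHyper(
            delta=data.p + 3.0, p=data.p, n=data.n, D=np.eye(data.p)
        )
        a = cg.log_marginal_likelihood(stats, h_fast)
        b = cg.log_marginal_likelihood(stats, h_dense)
        assert abs(a - b) < 1e-8


class TestEmpiricalBayes:
    def test_matches_fine_grid_search(self, gaussian_data):
        data = cg.standardize(gaussian_data)
        stats = cg.sufficient_stats(data)
        hyper = cg.fit_delta_empirical_bayes(data)
        fine = np.linspace(*ALPHA_BOUNDS, 10_000)
        vals = cg.log_ml_curve(stats, fine)
        alpha_star = fine[np.argmax(vals)]
        spacing = fine[1] - fine[0]
        assert abs(hyper.alpha - alpha_star) < max(spacing * 2, 1e-4)

    def test_returned_point_beats_interval_ends(self, gaussian_data):
        data = cg.standardize(gaussian_data)
        stats = cg.sufficient_stats(data)
        hyper = cg.fit_delta_empirical_bayes(data)
        best = cg.log_marginal_likelihood(stats, hyper)
        for a in (0.01, 0.99):
            h = cg.GCHyper.from_alpha(a, data.p, data.n)
            assert best >= cg.log_marginal_likelihood(stats, h)

    def test_alpha_delta_mutually_consistent(self, gaussian_data):
        data = cg.standardize(gaussian_data)
        hyper = cg.fit_delta_empirical_bayes(data)
        assert 0 < hyper.alpha < 1
        assert hyper.delta > data.p + 1
        round_trip = cg.GCHyper.from_alpha(hyper.alpha, data.p, data.n)
        assert abs(round_trip.delta - hyper.delta) < 1e-8


class TestGCHyperValidation:
    def test_delta_must_exceed_p_plus_1(self):
        with pytest.raises(ValueError, match="delta"):
            cg.GCHyper(delta=5.0, p=5, n=10)

    def test_non_pd_D_rejected(self):
        D = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="positive definite"):
            cg.GCHyper(delta=10.0, p=3, n=5, D=D)
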