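"""SVD reduction, conjugate posterior, Gibbs sampler and back-transform."""

import numpy as np
import pytest
from scipy import stats

from brsvd.core import (GibbsConfig, PriorSpec, backtransform_beta,
                        build_design, compute_svd, fit_brsvd, gibbs_sample,
                        mle_superfactor, posterior_update)
from brsvd.io import GenotypeMatrix, PhenotypeTable

FLAT = PriorSpec(m=1e12)


def _random_svd(rng, n=5, p=40):
    X = rng.standard_normal((n, p))
    return X, compute_svd(X)


class TestBuildDesign:
    def test_column_order_and_centering(self, tiny_genotypes, tiny_phenotypes):
        xd, y = build_design(tiny_genotypes, tiny_phenotypes, center=True)
        assert xd.column_ids == ["snp1", "snp2", "sex"]
        assert xd.n_snps == 2 and xd.n_covariates == 1
        np.testing.assert_allclose(xd.X.mean(axis=0), 0, atol=1e-12)
        assert abs(y.mean()) < 1e-12

    def test_uncentered_keeps_raw_values(self, tiny_genotypes, tiny_phenotypes):
        xd, y = build_design(tiny_genotypes, tiny_phenotypes, center=False)
        np.testing.assert_array_equal(xd.X[:, :2], tiny_genotypes.dosages)
        np.testing.assert_array_equal(y, tiny_phenotypes.trait)

    def test_too_few_samples(self):
        g = GenotypeMatrix(dosages=np.array([[1.0], [0.0]]),
                           sample_ids=["a", "b"], snp_ids=["v"])
        p = PhenotypeTable(sample_ids=["a", "b"], trait=np.array([1.0, 2.0]),
                           covariates=np.empty((2, 0)), covariate_names=[])
        with pytest.raises(ValueError, match="at least 3"):
            build_design(g, p)

    def test_unaligned_inputs_rejected(self, tiny_genotypes, tiny_phenotypes):
        bad = PhenotypeTable(sample_ids=["s2", "s1", "s3"],
                             trait=tiny_phenotypes.trait,
                             covariates=tiny_phenotypes.covariates,
                             covariate_names=["sex"])
        with pytest.raises(ValueError, match="align"):
            build_design(tiny_genotypes, bad)


class TestComputeSVD:
    def test_identity_matrix(self):
        svd = compute_svd(np.eye(2))
        np.testing.assert_allclose(svd.d, [1, 1])
        assert svd.r == 2

    def test_rank_one_all_ones(self):
        svd = compute_svd(np.ones((3, 5)))
        assert svd.r == 1
        assert svd.d[0] == pytest.approx(np.sqrt(15))

    def test_factors_verified_against_eigendecomposition(self, rng):
        """A and d must match the eigendecomposition of X'X (independent
        oracle) and reconstruct X: X = F D A'."""
        X, svd = _random_svd(rng)
        np.testing.assert_allclose(svd.A.T @ svd.A, np.eye(svd.r), atol=1e-12)
        np.testing.assert_allclose(svd.F.T @ svd.F, np.eye(svd.r), atol=1e-12)
        recon = svd.F @ (np.diag(svd.d) @ svd.A.T)
        assert np.linalg.norm(X - recon) < 1e-10
        evals = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1][: svd.r]
        np.testing.assert_allclose(svd.d**2, evals, rtol=1e-10)

    def test_rank_truncation_drops_null_directions(self, rng):
        X = rng.standard_normal((6, 3))
        X = np.column_stack([X, X[:, 0], np.zeros(6)])  # duplicate + zero col
        svd = compute_svd(X)
        assert svd.r == 3
        assert np.all(svd.d > svd.tol * svd.d[0])

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="rank 0|zero"):
            compute_svd(np.zeros((4, 4)))


class TestMLESuperfactor:
    def test_zero_trait(self, rng):
        _, svd = _random_svd(rng)
        np.testing.assert_array_equal(mle_superfactor(svd, np.zeros(5)), 0)

    def test_exact_interpolation(self, rng):
        _, svd = _random_svd(rng)
        gamma0 = rng.standard_normal(svd.r)
        y = svd.L() @ gamma0
        np.testing.assert_allclose(mle_superfactor(svd, y), gamma0, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        """gamma_hat must equal (L'L)^{-1} L'y computed explicitly."""
        X = rng.standard_normal((6, 4))
        svd = compute_svd(X)
        y = rng.standard_normal(6)
        L = svd.L()
        expected = np.linalg.solve(L.T @ L, L.T @ y)
        np.testing.assert_allclose(mle_superfactor(svd, y), expected, atol=1e-10)

    def test_length_mismatch(self, rng):
        _, svd = _random_svd(rng)
        with pytest.raises(ValueError):
            mle_superfactor(svd, np.zeros(7))


class TestPosteriorUpdate:
    def test_flat_prior_limit_is_mle(self, rng):
        _, svd = _random_svd(rng)
        y = rng.standard_normal(5)
        post = posterior_update(svd, y, FLAT)
        np.testing.assert_allclose(post.gamma_tilde, mle_superfactor(svd, y),
                                   rtol=1e-6)

    def test_zero_data_zero_prior_mean(self, rng):
        _, svd = _random_svd(rng)
        post = posterior_update(svd, np.zeros(5), PriorSpec())
        np.testing.assert_array_equal(post.gamma_tilde, 0)
        assert post.b_post == pytest.approx(1.0)  # just the prior b

    def test_v_diag_bounded_by_m(self, rng):
        _, svd = _random_svd(rng)
        prior = PriorSpec(m=2.0)
        post = posterior_update(svd, rng.standard_normal(5), prior)
        assert np.all(post.v_diag > 0) and np.all(post.v_diag <= prior.m)

    def test_grid_integration_oracle_r1(self):
        """n=4, single-column design: the posterior mean of gamma from
        brute-force numerical integration of likelihood x prior matches
        the closed-form gamma_tilde."""
        x = np.array([[1.0], [2.0], [-1.0], [0.5]])
        y = np.array([0.8, 2.1, -1.2, 0.3])
        prior = PriorSpec(beta_star=0.0, m=4.0, a=2.0, b=1.5)
        svd = compute_svd(x)
        post = posterior_update(svd, y, prior)

        gam = np.linspace(-4, 6, 801)
        sig2 = np.linspace(1e-3, 25, 1200)
        G, S2 = np.meshgrid(gam, sig2, indexing="ij")
        L = svd.L()[:, 0]
        n = 4
        rss = ((y[None, None, :] - G[..., None] * L[None, None, :]) ** 2).sum(-1)
        log_lik = -n / 2 * np.log(S2) - rss / (2 * S2)
        log_prior = (-0.5 * np.log(S2) - (G - 0.0) ** 2 / (2 * S2 * prior.m)
                     - (prior.a / 2 + 1) * np.log(S2) - prior.b / (2 * S2))
        w = np.exp(log_lik + log_prior - (log_lik + log_prior).max())
        w /= w.sum()
        grid_mean = float((w.sum(axis=1) * gam).sum())
        assert grid_mean == pytest.approx(post.gamma_tilde[0], abs=2e-2)

    def test_invalid_prior(self):
        with pytest.raises(ValueError):
            PriorSpec(m=-1.0)
        with pytest.raises(ValueError):
            PriorSpec(a=0.0)


class TestGibbsSampler:
    @staticmethod
    def _instance(rng, n=50, p=50, prior=None, cfg=None):
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        svd = compute_svd(X)
        prior = prior or PriorSpec(m=5.0, a=3.0, b=2.0)
        post = posterior_update(svd, y, prior)
        cfg = cfg or GibbsConfig(n_iter=4000, burn_in=1000, seed=99)
        draws = gibbs_sample(post, svd, y, prior, cfg)
        return svd, y, prior, post, draws

    def test_same_seed_bitwise_identical(self, rng):
        X = rng.standard_normal((10, 8))
        y = rng.standard_normal(10)
        svd = compute_svd(X)
        prior = PriorSpec()
        post = posterior_update(svd, y, prior)
        cfg = GibbsConfig(n_iter=300, burn_in=100, seed=5)
        d1 = gibbs_sample(post, svd, y, prior, cfg)
        d2 = gibbs_sample(post, svd, y, prior, cfg)
        assert np.array_equal(d1.gamma_draws, d2.gamma_draws)
        assert np.array_equal(d1.sigma2_draws, d2.sigma2_draws)

    def test_gamma_mean_matches_analytic_within_mc_error(self, rng):
        """Sampler means agree with the conjugate closed form within 4
        Monte-Carlo standard errors, coordinate-wise."""
        svd, y, prior, post, draws = self._instance(rng)
        S = draws.n_draws
        mc_mean = draws.gamma_draws.mean(axis=0)
        mc_se = draws.gamma_draws.std(axis=0, ddof=1) / np.sqrt(S)
        z = np.abs(mc_mean - post.gamma_tilde) / mc_se
        assert z.max() < 4.0

    def test_sigma2_mean_matches_analytic_within_mc_error(self, rng):
        svd, y, prior, post, draws = self._instance(rng)
        S = draws.n_draws
        analytic = post.b_post / (post.a_post - 2)
        mc_se = draws.sigma2_draws.std(ddof=1) / np.sqrt(S)
        assert abs(draws.sigma2_draws.mean() - analytic) < 4 * mc_se

    def test_marginal_is_student_t(self, rng):
        """Standardized gamma draws follow Student-t with n + a df."""
        n = 30
        X = rng.standard_normal((n, 2))
        y = X @ np.array([0.7, -0.3]) + rng.standard_normal(n)
        svd = compute_svd(X)
        prior = PriorSpec(m=10.0, a=4.0, b=2.0)
        post = posterior_update(svd, y, prior)
        cfg = GibbsConfig(n_iter=9000, burn_in=1000, seed=21)
        draws = gibbs_sample(post, svd, y, prior, cfg)
        scale = post.gamma_marginal_scale()
        std = ((draws.gamma_draws - post.gamma_tilde) / scale).ravel()
        ks = stats.kstest(std, "t", args=(post.df_t,))
        assert ks.pvalue > 0.01

    def test_small_chain_rejected(self):
        with pytest.raises(ValueError, match="100"):
            GibbsConfig(n_iter=150, burn_in=100)


class TestBacktransform:
    def test_zero_gamma(self, rng):
        _, svd = _random_svd(rng)
        np.testing.assert_array_equal(
            backtransform_beta(np.zeros(svd.r), svd).beta, 0)

    def test_reproduces_gamma_and_norm(self, rng):
        _, svd = _random_svd(rng)
        gamma = rng.standard_normal(svd.r)
        beta = backtransform_beta(gamma, svd).beta
        np.testing.assert_allclose(svd.A.T @ beta, gamma, atol=1e-8)
        assert np.linalg.norm(beta) == pytest.approx(np.linalg.norm(gamma),
                                                     abs=1e-10)

    def test_minimum_norm_property(self, rng):
        """||A gamma|| <= ||A gamma + (I - A A') z|| for any z, with
        equality iff the complement part vanishes (Pythagoras)."""
        _, svd = _random_svd(rng)
        gamma = rng.standard_normal(svd.r)
        beta = svd.A @ gamma
        P_perp = np.eye(svd.p) - svd.A @ svd.A.T
        for _ in range(5):
            z = rng.standard_normal(svd.p)
            other = beta + P_perp @ z
            assert np.linalg.norm(beta) <= np.linalg.norm(other) + 1e-12
            if np.linalg.norm(P_perp @ z) > 1e-8:
                assert np.linalg.norm(beta) < np.linalg.norm(other)

    def test_determined_system_equals_ols(self, rng):
        """k <= n, full column rank, near-flat prior: beta is OLS."""
        n, p = 50, 3
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        svd = compute_svd(X)
        post = posterior_update(svd, y, FLAT)
        beta = backtransform_beta(post.gamma_tilde, svd).beta
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, ols, rtol=1e-6)


class TestFitBRSVD:
    def test_noiseless_determined_recovery(self, rng):
        n, k = 50, 3
        dos = rng.integers(0, 3, size=(n, k)).astype(float)
        beta0 = np.array([1.0, -0.5, 2.0])
        y = dos @ beta0
        g = GenotypeMatrix(dosages=dos, sample_ids=[f"s{i}" for i in range(n)],
                           snp_ids=["a", "b", "c"])
        p = PhenotypeTable(sample_ids=g.sample_ids, trait=y,
                           covariates=np.empty((n, 0)), covariate_names=[])
        beta, draws, post = fit_brsvd(g, p, prior=FLAT)
        np.testing.assert_allclose(beta.beta, beta0, atol=1e-6)

    def test_causal_snps_rank_high(self, small_study):
        study = small_study
        beta, _, _ = fit_brsvd(study.genotypes, study.phenotypes[0],
                               cfg=GibbsConfig(n_iter=500, burn_in=100, seed=1))
        k = study.genotypes.n_snps
        order = np.argsort(-np.abs(beta.beta[:k]))
        top = {study.genotypes.snp_ids[j] for j in order[: max(3, k // 20)]}
        assert study.causal_ids <= top

    def test_row_permutation_invariance(self, small_study, rng):
        g, p = small_study.genotypes, small_study.phenotypes[0]
        beta1, _, _ = fit_brsvd(g, p, cfg=GibbsConfig(n_iter=500, burn_in=100))
        perm = rng.permutation(g.n_samples)
        beta2, _, _ = fit_brsvd(g.take_samples(perm), p.take_samples(perm),
                                cfg=GibbsConfig(n_iter=500, burn_in=100))
        np.testing.assert_allclose(beta1.beta, beta2.beta, atol=1e-8)

    def test_scale_equivariance(self, small_study):
        g, p = small_study.genotypes, small_study.phenotypes[0]
        cfg = GibbsConfig(n_iter=500, burn_in=100)
        beta1, _, _ = fit_brsvd(g, p, prior=FLAT, cfg=cfg)
        p3 = PhenotypeTable(sample_ids=p.sample_ids, trait=3.0 * p.trait,
                            covariates=p.covariates,
                            covariate_names=p.covariate_names)
        beta3, _, _ = fit_brsvd(g, p3, prior=FLAT, cfg=cfg)
        np.testing.assert_allclose(beta3.beta, 3.0 * beta1.beta, atol=1e-8)

    def test_reduced_and_full_model_predictions_agree(self, small_study):
        g, p = small_study.genotypes, small_study.phenotypes[0]
        xd, y = build_design(g, p)
        svd = compute_svd(xd)
        gamma = mle_superfactor(svd, y)
        beta = backtransform_beta(gamma, svd, source="mle").beta
        np.testing.assert_allclose(svd.L() @ gamma, xd.X @ beta, atol=1e-8)
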