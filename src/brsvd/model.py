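"""Model/Results interface over the BRSVD engine.

``BRSVD`` is constructed from aligned genotype and phenotype containers
(or plain DataFrames); ``fit()`` runs the SVD reduction, the conjugate
posterior update and the Gibbs sampler, and returns a ``BRSVDResults``
carrying the per-SNP effect estimates, posterior draws, diagnostics and a
``summary()`` table. The permutation significance test hangs off the
results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import core
from .core import (BetaEstimate, GibbsConfig, GibbsDraws, PosteriorParams,
                   PriorSpec, SVDFactors)
from .io import GenotypeMatrix, PhenotypeTable, align_samples
from .permutation import (PermutationConfig, PermutationResult,
                          empirical_pvalues, lambda_statistics,
                          permutation_deltas)

__all__ = ["BRSVD", "BRSVDResults"]


class BRSVD:
    """Bayesian regression with SVD dimension reduction for k >> n.

    Parameters
    ----------
    genotypes, phenotypes :
        Sample-aligned containers (mismatched ids are aligned on shared
        samples automatically).
    prior :
        Conjugate normal--inverse-gamma hyperparameters; default
        ``PriorSpec(beta_star=0, m=1000, a=1, b=1)`` (weakly informative).
    center :
        Mean-center the trait and every design column (absorbs the
        intercept; default True).
    rank_tol :
        Relative singular-value truncation tolerance (default
        ``max(n, p) * eps``).

    Examples
    --------
    >>> model = BRSVD(genotypes, phenotypes)
    >>> res = model.fit(seed=1)
    >>> res.snp_effects.abs().nlargest(10)
    >>> perm = res.permutation_test(J=1000, seed=1)
    """

    def __init__(self, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                 prior: PriorSpec | None = None, center: bool = True,
                 rank_tol: float | None = None):
        if genotypes.sample_ids != phenotypes.sample_ids:
            genotypes, phenotypes = align_samples(genotypes, phenotypes)
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.prior = prior or PriorSpec()
        self.center = center
        self.rank_tol = rank_tol
        self.design, self.endog = core.build_design(genotypes, phenotypes,
                                                    center=center)
        self._svd: SVDFactors | None = None

    @classmethod
    def from_dataframe(cls, geno_df: pd.DataFrame, pheno_df: pd.DataFrame,
                       trait: str, covariates: list[str] | None = None,
                       **kwargs) -> "BRSVD":
        """Build from DataFrames indexed by sample id.

        ``geno_df``: samples x SNPs dosage frame; ``pheno_df`` holds the
        trait column and any covariate columns, same index.
        """
        covariates = covariates or []
        g = GenotypeMatrix(dosages=geno_df.to_numpy(dtype=float),
                           sample_ids=[str(s) for s in geno_df.index],
                           snp_ids=[str(s) for s in geno_df.columns])
        p = PhenotypeTable(sample_ids=[str(s) for s in pheno_df.index],
                           trait=pheno_df[trait].to_numpy(dtype=float),
                           covariates=pheno_df[covariates].to_numpy(dtype=float)
                           if covariates else np.empty((len(pheno_df), 0)),
                           covariate_names=covariates)
        return cls(g, p, **kwargs)

    @property
    def svd(self) -> SVDFactors:
        if self._svd is None:
            self._svd = core.compute_svd(self.design, rank_tol=self.rank_tol)
        return self._svd

    def fit(self, n_iter: int = 2000, burn_in: int = 500, thin: int = 1,
            seed: int = 0) -> "BRSVDResults":
        cfg = GibbsConfig(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
        post = core.posterior_update(self.svd, self.endog, self.prior)
        draws = core.gibbs_sample(post, self.svd, self.endog, self.prior, cfg)
        beta = core.backtransform_beta(post.gamma_tilde, self.svd,
                                       source="posterior_mean")
        return BRSVDResults(self, beta, draws, post)


class BRSVDResults:
    """Fit results: per-SNP effects, posterior draws and diagnostics.

    ``params`` is the analytic posterior-mean effect vector (exact under
    conjugacy); the Gibbs draws carry the joint posterior of the
    superfactors and the noise variance for interval estimates.
    """

    def __init__(self, model: BRSVD, beta: BetaEstimate, draws: GibbsDraws,
                 posterior: PosteriorParams):
        self.model = model
        self._beta = beta
        self.draws = draws
        self.posterior = posterior
        self.params = pd.Series(beta.beta, index=model.design.column_ids,
                                name="beta")

    @property
    def snp_effects(self) -> pd.Series:
        return self.params.iloc[: self.model.design.n_snps]

    @property
    def covariate_effects(self) -> pd.Series:
        return self.params.iloc[self.model.design.n_snps:]

    @property
    def sigma2_mean(self) -> float:
        return float(self.draws.sigma2_draws.mean())

    def beta_draws(self, columns: list[str] | None = None) -> pd.DataFrame:
        """Posterior draws of beta for selected columns (A gamma per draw)."""
        ids = columns if columns is not None else self.model.design.column_ids
        idx = [self.model.design.column_ids.index(c) for c in ids]
        sub = self.model.svd.A[idx] @ self.draws.gamma_draws.T
        return pd.DataFrame(sub.T, columns=ids)

    def conf_int(self, alpha: float = 0.05,
                 columns: list[str] | None = None) -> pd.DataFrame:
        """Equal-tailed posterior credible intervals from the Gibbs draws."""
        bd = self.beta_draws(columns)
        lo = bd.quantile(alpha / 2)
        hi = bd.quantile(1 - alpha / 2)
        return pd.DataFrame({"lower": lo, "upper": hi})

    def permutation_test(self, J: int = 1000, seed: int = 0,
                         estimator: str = "posterior_mean") -> PermutationResult:
        """Empirical per-SNP p-values by trait permutation (Lambda vs N(0,1))."""
        cfg = PermutationConfig(J=J, seed=seed, estimator=estimator)
        deltas, beta_raw, info = permutation_deltas(
            self.model.genotypes, self.model.phenotypes,
            prior=self.model.prior, cfg=cfg, center=self.model.center,
            rank_tol=self.model.rank_tol)
        lam = lambda_statistics(deltas)
        return PermutationResult(
            column_ids=info.column_ids, n_snps=info.n_snps,
            beta_raw=beta_raw, delta_mean=deltas.mean(axis=1),
            delta_sd=deltas.std(axis=1, ddof=1), lambda_=lam,
            pvalues=empirical_pvalues(lam), J_used=J, seed_used=seed)

    def summary(self, top: int = 10) -> str:
        d = self.model.design
        svd = self.model.svd
        prior = self.model.prior
        lines = [
            "BRSVD Regression Results",
            "=" * 58,
            f"{'No. samples:':<28}{d.n_samples}",
            f"{'No. SNPs:':<28}{d.n_snps}",
            f"{'No. covariates:':<28}{d.n_covariates}",
            f"{'Effective rank r:':<28}{svd.r}",
            f"{'Prior (m, a, b):':<28}({prior.m:g}, {prior.a:g}, {prior.b:g})",
            f"{'Gibbs draws retained:':<28}{self.draws.n_draws}",
            f"{'sigma^2 posterior mean:':<28}{self.sigma2_mean:.6g}",
            f"{'t marginal df (n + a):':<28}{self.posterior.df_t:g}",
            "-" * 58,
            f"Top {top} SNP effects by |posterior mean|:",
            f"{'snp_id':<20}{'beta':>12}",
        ]
        for sid, b in self.snp_effects.abs().nlargest(top).items():
            lines.append(f"{sid:<20}{self.params[sid]:>12.6f}")
        if d.n_covariates:
            lines.append("-" * 58)
            lines.append(f"{'covariate':<20}{'beta':>12}")
            for cid, b in self.covariate_effects.items():
                lines.append(f"{cid:<20}{b:>12.6f}")
        lines.append("=" * 58)
        return "\n".join(lines)
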