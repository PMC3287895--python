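"""Core engine: SVD reduction, conjugate posterior, Gibbs sampler, back-transform.

The regression of a quantitative trait y on a design matrix X (k SNP dosage
columns followed by c covariate columns, k + c = p, typically p >> n) is
reduced by the singular value decomposition X' = A D F' to an n-dimensional
"superfactor" model

    y = L gamma + eps,    L = F D,    gamma = A' beta,

on which exact conjugate normal--inverse-gamma inference is available:
because L'L = D^2 is diagonal, the posterior of gamma given sigma^2 is a
product of independent normals and the Gibbs sampler mixes in one step.
Per-SNP effects are recovered as the minimum-Euclidean-norm solution of
gamma = A' beta, namely beta = A gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "SVDFactors",
    "PriorSpec",
    "PosteriorParams",
    "GibbsConfig",
    "GibbsDraws",
    "BetaEstimate",
    "build_design",
    "compute_svd",
    "mle_superfactor",
    "posterior_update",
    "gibbs_sample",
    "backtransform_beta",
    "fit_brsvd",
]


@dataclass
class DesignMatrix:
    """n x p design: k SNP dosage columns then c covariate columns."""

    X: np.ndarray
    column_ids: list[str]
    n_snps: int
    n_covariates: int
    centered: bool
    column_means: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        p = self.X.shape[1]
        if p != self.n_snps + self.n_covariates:
            raise ValueError("p != k + c")
        if len(self.column_ids) != p or len(set(self.column_ids)) != p:
            raise ValueError("column_ids must be unique and length p")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class SVDFactors:
    """Thin SVD of X written as X' = A D F' (so X = F D A', L = F D).

    A is p x r and F is n x r, both with orthonormal columns; d holds the r
    retained singular values in non-increasing order. r is the effective
    rank after discarding singular values below ``tol * d[0]``.
    """

    A: np.ndarray
    d: np.ndarray
    F: np.ndarray
    r: int
    tol: float

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[0]

    def L(self) -> np.ndarray:
        return self.F * self.d


@dataclass
class PriorSpec:
    """Conjugate hyperparameters: beta | sigma^2 ~ N(beta_star, sigma^2 m I),
    sigma^2 ~ InvGamma(shape a/2, scale b/2).

    The inverse-gamma scale is chosen so the marginal posterior of each
    superfactor coordinate is Student-t with exactly n + a degrees of
    freedom. ``beta_star`` may be a scalar (broadcast over columns).
    """

    beta_star: float | np.ndarray = 0.0
    m: float = 1000.0
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError(f"prior hyperparameters m, a, b must be positive "
                             f"(got m={self.m}, a={self.a}, b={self.b})")

    def beta_star_vector(self, p: int) -> np.ndarray:
        bs = np.asarray(self.beta_star, dtype=float)
        if bs.ndim == 0:
            return np.full(p, float(bs))
        if bs.shape != (p,):
            raise ValueError(f"beta_star has length {bs.shape[0]}, expected {p}")
        return bs


@dataclass
class PosteriorParams:
    """Closed-form reduced-model posterior.

    gamma | sigma^2, y ~ N(gamma_tilde, sigma^2 diag(v_diag));
    sigma^2 | y ~ InvGamma(shape a_post/2, scale b_post/2);
    marginally each gamma_i is Student-t with df_t = n + a degrees of
    freedom, location gamma_tilde_i and scale sqrt(b_post/a_post * v_diag_i).
    """

    gamma_star: np.ndarray
    gamma_tilde: np.ndarray
    v_diag: np.ndarray
    a_post: float
    b_post: float
    df_t: float

    def sigma2_mean(self) -> float:
        """Posterior mean of sigma^2 (exists for a_post > 2)."""
        if self.a_post <= 2:
            raise ValueError("posterior mean of sigma^2 requires a_post > 2")
        return self.b_post / (self.a_post - 2)

    def gamma_marginal_scale(self) -> np.ndarray:
        return np.sqrt(self.b_post / self.a_post * self.v_diag)


@dataclass
class GibbsConfig:
    n_iter: int = 2000
    burn_in: int = 500
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin <= 0:
            raise ValueError("thin must be positive")
        if self.n_draws < 100:
            raise ValueError(
                f"retained draw count {self.n_draws} < 100; increase n_iter")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class GibbsDraws:
    """Retained joint draws of (gamma, sigma^2) from the Gibbs sampler."""

    gamma_draws: np.ndarray  # S x r
    sigma2_draws: np.ndarray  # S
    seed_used: int

    @property
    def n_draws(self) -> int:
        return self.gamma_draws.shape[0]


@dataclass
class BetaEstimate:
    """Per-column effect vector beta = A gamma (minimum-norm back-transform)."""

    beta: np.ndarray
    source: str  # "mle" or "posterior_mean"


def build_design(g: GenotypeMatrix, p: PhenotypeTable, center: bool = True
                 ) -> tuple[DesignMatrix, np.ndarray]:
    """Assemble X = [SNP dosages | covariates] and the trait vector.

    With ``center=True`` every column of X and the trait are mean-centered
    (absorbing the intercept) and the subtracted means recorded. Constant
    columns are kept — they contribute a zero singular direction — but
    logged.
    """
    if g.sample_ids != p.sample_ids:
        raise ValueError("genotypes and phenotypes are not sample-aligned; "
                         "call align_samples first")
    n = g.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    X = np.column_stack([g.dosages, p.covariates]) if p.n_covariates else g.dosages.copy()
    column_ids = list(g.snp_ids) + list(p.covariate_names)
    y = p.trait.astype(float).copy()
    const = np.flatnonzero(np.ptp(X, axis=0) == 0)
    if const.size:
        logger.info("%d constant design column(s), e.g. %s (kept; zero singular direction)",
                    const.size, column_ids[const[0]])
    if center:
        column_means = X.mean(axis=0)
        X = X - column_means
        y = y - y.mean()
    else:
        column_means = np.zeros(X.shape[1])
    xd = DesignMatrix(X=X, column_ids=column_ids, n_snps=g.n_snps,
                      n_covariates=p.n_covariates, centered=center,
                      column_means=column_means)
    logger.info("design: n=%d, k=%d SNPs, c=%d covariates, p=%d columns",
                n, g.n_snps, p.n_covariates, xd.n_columns)
    return xd, y


def compute_svd(Xd: DesignMatrix | np.ndarray, rank_tol: float | None = None) -> SVDFactors:
    """Thin SVD of the design with rank truncation.

    Singular values below ``rank_tol * d[0]`` are discarded (default
    ``max(n, p) * machine-eps``), so constant or duplicate SNP columns do
    not pollute the reduced model with numerically-zero directions.
    """
    X = Xd.X if isinstance(Xd, DesignMatrix) else np.asarray(Xd, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite entries")
    F_full, d_full, At_full = np.linalg.svd(X, full_matrices=False)
    if d_full.size == 0 or d_full[0] == 0.0:
        raise ValueError("design matrix is identically zero (rank 0)")
    if rank_tol is None:
        rank_tol = max(X.shape) * np.finfo(float).eps
    r = int(np.sum(d_full > rank_tol * d_full[0]))
    if r == 0:
        raise ValueError("all singular values below truncation tolerance")
    n_discarded = d_full.size - r
    if n_discarded:
        logger.info("discarded %d singular direction(s) below tol=%.3g", n_discarded, rank_tol)
    return SVDFactors(A=At_full[:r].T.copy(), d=d_full[:r].copy(),
                      F=F_full[:, :r].copy(), r=r, tol=float(rank_tol))


def mle_superfactor(svd: SVDFactors, y: np.ndarray) -> np.ndarray:
    """Least-squares / ML estimate of gamma: D^{-1} F' y."""
    y = np.asarray(y, dtype=float)
    if y.shape != (svd.n,):
        raise ValueError(f"trait length {y.shape} does not match n={svd.n}")
    return (svd.F.T @ y) / svd.d


def posterior_update(svd: SVDFactors, y: np.ndarray, prior: PriorSpec) -> PosteriorParams:
    """Conjugate update of the reduced model y = L gamma + eps.

    Since A has orthonormal columns, the prior beta | sigma^2 ~
    N(beta_star, sigma^2 m I_p) induces gamma | sigma^2 ~
    N(A' beta_star, sigma^2 m I_r), and because L'L = D^2 the posterior
    covariance stays diagonal:

        v_i           = 1 / (d_i^2 + 1/m)
        gamma_tilde   = diag(v) (D F'y + gamma_star / m)
        a_post        = a + n                      (df scale; IG shape a_post/2)
        b_post        = b + ||y - L gamma_tilde||^2
                          + ||gamma_tilde - gamma_star||^2 / m
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (svd.n,):
        raise ValueError(f"trait length {y.shape} does not match n={svd.n}")
    beta_star = prior.beta_star_vector(svd.p)
    gamma_star = svd.A.T @ beta_star
    v = 1.0 / (svd.d**2 + 1.0 / prior.m)
    Fty = svd.F.T @ y
    gamma_tilde = v * (svd.d * Fty + gamma_star / prior.m)
    resid = y - svd.F @ (svd.d * gamma_tilde)
    b_post = prior.b + resid @ resid + (gamma_tilde - gamma_star) @ (gamma_tilde - gamma_star) / prior.m
    n = svd.n
    return PosteriorParams(gamma_star=gamma_star, gamma_tilde=gamma_tilde,
                           v_diag=v, a_post=prior.a + n, b_post=float(b_post),
                           df_t=prior.a + n)


def gibbs_sample(post: PosteriorParams, svd: SVDFactors, y: np.ndarray,
                 prior: PriorSpec, cfg: GibbsConfig) -> GibbsDraws:
    """Gibbs sampler alternating the two full conditionals.

    gamma | sigma^2, y ~ N(gamma_tilde, sigma^2 diag(v));
    sigma^2 | gamma, y ~ InvGamma(shape (a + n + r)/2,
                                  scale (b + ||y - L gamma||^2
                                           + ||gamma - gamma_star||^2 / m)/2).

    The chain starts from the maximum-likelihood superfactor. Identical
    seeds give bitwise-identical draws.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    r, n = svd.r, svd.n
    d, F = svd.d, svd.F
    gamma_star, gamma_tilde, v = post.gamma_star, post.gamma_tilde, post.v_diag
    sqrt_v = np.sqrt(v)
    yty = y @ y
    dFty = d * (F.T @ y)
    shape = (prior.a + n + r) / 2.0
    gamma = mle_superfactor(svd, y)

    S = cfg.n_draws
    gamma_draws = np.empty((S, r))
    sigma2_draws = np.empty(S)
    s = 0
    for t in range(cfg.n_iter):
        # ||y - L gamma||^2 expanded through the diagonal reduction
        rss = yty - 2.0 * (gamma @ dFty) + np.sum((d * gamma) ** 2)
        dev = gamma - gamma_star
        scale = (prior.b + rss + dev @ dev / prior.m) / 2.0
        sigma2 = scale / rng.gamma(shape)
        gamma = gamma_tilde + np.sqrt(sigma2) * sqrt_v * rng.standard_normal(r)
        if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            gamma_draws[s] = gamma
            sigma2_draws[s] = sigma2
            s += 1
    assert s == S
    return GibbsDraws(gamma_draws=gamma_draws, sigma2_draws=sigma2_draws,
                      seed_used=cfg.seed)


def backtransform_beta(gamma: np.ndarray, svd: SVDFactors,
                       source: str = "posterior_mean") -> BetaEstimate:
    """Map a superfactor vector back to per-column effects: beta = A gamma.

    Choosing the generalized inverse of A' as A gives the unique
    minimum-Euclidean-norm solution of gamma = A' beta; since A has
    orthonormal columns, ||beta|| = ||gamma|| and A' beta reproduces gamma
    exactly.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape != (svd.r,):
        raise ValueError(f"gamma length {gamma.shape} does not match rank r={svd.r}")
    if source not in ("mle", "posterior_mean"):
        raise ValueError(f"unknown source {source!r}")
    return BetaEstimate(beta=svd.A @ gamma, source=source)


def fit_brsvd(g: GenotypeMatrix, p: PhenotypeTable,
              prior: PriorSpec | None = None,
              cfg: GibbsConfig | None = None,
              center: bool = True,
              rank_tol: float | None = None,
              ) -> tuple[BetaEstimate, GibbsDraws, PosteriorParams]:
    """Full pipeline: design -> SVD -> conjugate posterior -> Gibbs -> beta.

    The reported beta is the analytic posterior mean A gamma_tilde (exact
    under conjugacy); the Gibbs draws quantify posterior uncertainty of
    (gamma, sigma^2).
    """
    prior = prior or PriorSpec()
    cfg = cfg or GibbsConfig()
    xd, y = build_design(g, p, center=center)
    svd = compute_svd(xd, rank_tol=rank_tol)
    logger.info("rank r=%d of min(n,p)=%d", svd.r, min(xd.n_samples, xd.n_columns))
    post = posterior_update(svd, y, prior)
    draws = gibbs_sample(post, svd, y, prior, cfg)
    beta = backtransform_beta(post.gamma_tilde, svd, source="posterior_mean")
    return beta, draws, post
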