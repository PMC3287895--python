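"""Synthetic genotype/phenotype generator and benchmark runner.

Emulates the structure of a sequence-data association study: a panel of
mostly-rare biallelic SNPs in Hardy-Weinberg proportions with no linkage
disequilibrium, three covariates (sex, age, smoking), a sparse causal SNP
set shared across phenotype replicates, and a quantitative trait

    y = G beta_true + C b_cov + eps,   eps ~ N(0, noise_sd^2),

where only the noise draw differs between replicates. The benchmark runner
scores each method's selected SNPs against the causal truth and averages
the confusion-matrix rates over replicates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .baselines import genomewide_threshold, scan_dataframe, single_snp_scan
from .core import GibbsConfig, PriorSpec
from .io import GenotypeMatrix, PhenotypeTable
from .metrics import (ConfusionMetrics, average_over_replicates,
                      confusion_metrics, select_significant)
from .permutation import PermutationConfig, run_brsvd_association

logger = logging.getLogger(__name__)

__all__ = ["SimulationSpec", "SimulatedStudy", "simulate_genotypes",
           "simulate_covariates", "simulate_trait", "simulate_study",
           "run_benchmark", "desk_scale_spec", "gaw17_like_spec",
           "strong_effect_spec", "sensitivity_at_fpr"]

COVARIATE_NAMES = ["sex", "age", "smoking"]


@dataclass
class SimulationSpec:
    """Study-design parameters for the generator.

    Causal effect sizes are on the residual-sd scale of the trait
    (noise_sd defaults to 1). ``causal_min_maf`` restricts the causal draw
    to SNPs at or above that minor-allele frequency; 0 allows any SNP.
    """

    n: int = 200
    k: int = 1000
    maf_low: float = 0.005
    maf_high: float = 0.5
    n_causal: int = 5
    effect_size: float | np.ndarray = 0.5
    covariate_effects: tuple[float, float, float] = (0.2, 0.05, 0.2)
    noise_sd: float = 1.0
    n_replicates: int = 10
    seed: int = 0
    causal_min_maf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_causal > self.k:
            raise ValueError("n_causal cannot exceed k")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def desk_scale_spec(**overrides) -> SimulationSpec:
    """Desk-scale default: n=200, k=1000."""
    return replace(SimulationSpec(), **overrides)


def gaw17_like_spec(**overrides) -> SimulationSpec:
    """Preset mirroring the scale of the GAW17 unrelated-individuals panel:
    697 samples, 24,487 SNPs, 39 causal, 10 phenotype replicates."""
    spec = SimulationSpec(n=697, k=24487, n_causal=39, n_replicates=10)
    return replace(spec, **overrides)


def strong_effect_spec(**overrides) -> SimulationSpec:
    """Power-benchmark preset: n=300, k=1000, 5 common causal SNPs with
    effect 1.5 residual-sd per allele copy."""
    spec = SimulationSpec(n=300, k=1000, n_causal=5, effect_size=1.5,
                          noise_sd=1.0, causal_min_maf=0.05)
    return replace(spec, **overrides)


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    phenotypes: list[PhenotypeTable]
    causal_ids: set[str]
    true_beta: np.ndarray
    mafs: np.ndarray = field(default=None)  # type: ignore[assignment]


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator
                       ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hardy-Weinberg dosages: per SNP draw MAF ~ U(maf_low, maf_high),
    then dosages ~ Binomial(2, MAF) independently per sample.

    Monomorphic columns are redrawn up to 10 times, then accepted with a
    warning (unavoidable for very rare variants at small n). Returns the
    matrix and the generating MAF vector.
    """
    n, k = spec.n, spec.k
    mafs = rng.uniform(spec.maf_low, spec.maf_high, size=k)
    geno = rng.binomial(2, mafs, size=(n, k)).astype(float)
    n_stuck = 0
    for j in np.flatnonzero(np.ptp(geno, axis=0) == 0):
        for _ in range(10):
            col = rng.binomial(2, mafs[j], size=n).astype(float)
            if np.ptp(col) > 0:
                geno[:, j] = col
                break
        else:
            n_stuck += 1
    if n_stuck:
        warnings.warn(f"{n_stuck} SNP column(s) remained monomorphic after "
                      "10 redraws", stacklevel=2)
    width = len(str(k))
    snp_ids = [f"snp{j + 1:0{width}d}" for j in range(k)]
    sample_ids = [f"s{i + 1:0{len(str(n))}d}" for i in range(n)]
    g = GenotypeMatrix(dosages=geno, sample_ids=sample_ids, snp_ids=snp_ids)
    return g, mafs


def simulate_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sex ~ Bernoulli(0.5), age ~ Normal(50, 10), smoking ~ Bernoulli(0.3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    age = rng.normal(50.0, 10.0, size=n)
    smoking = rng.binomial(1, 0.3, size=n).astype(float)
    return np.column_stack([sex, age, smoking])


def _draw_causal(spec: SimulationSpec, mafs: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    eligible = np.flatnonzero(mafs >= spec.causal_min_maf)
    if eligible.size < spec.n_causal:
        raise ValueError(
            f"only {eligible.size} SNPs at MAF >= {spec.causal_min_maf}, "
            f"cannot draw {spec.n_causal} causal SNPs")
    return rng.choice(eligible, size=spec.n_causal, replace=False)


def simulate_trait(g: GenotypeMatrix, covariates: np.ndarray,
                   true_beta: np.ndarray, spec: SimulationSpec,
                   rng: np.random.Generator) -> PhenotypeTable:
    """One phenotype replicate: y = G beta_true + C b_cov + noise."""
    c_eff = np.asarray(spec.covariate_effects, dtype=float)
    y = g.dosages @ true_beta + covariates @ c_eff
    y = y + rng.normal(0.0, spec.noise_sd, size=g.n_samples)
    return PhenotypeTable(sample_ids=list(g.sample_ids), trait=y,
                          covariates=covariates,
                          covariate_names=list(COVARIATE_NAMES))


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Full study: genotypes, covariates, causal set (drawn once), and one
    phenotype replicate per noise stream.

    The genotype panel, covariates, causal set and effect sizes are shared
    across replicates; only the trait's noise differs, mirroring replicate
    phenotypes simulated on a fixed genotype panel.
    """
    root = np.random.SeedSequence(spec.seed)
    geno_ss, cov_ss, causal_ss, *rep_ss = root.spawn(3 + spec.n_replicates)
    g, mafs = simulate_genotypes(spec, np.random.default_rng(geno_ss))
    covariates = simulate_covariates(spec.n, np.random.default_rng(cov_ss))
    causal_idx = _draw_causal(spec, mafs, np.random.default_rng(causal_ss))
    true_beta = np.zeros(spec.k)
    effects = np.asarray(spec.effect_size, dtype=float)
    if effects.ndim == 0:
        effects = np.full(spec.n_causal, float(effects))
    if effects.shape != (spec.n_causal,):
        raise ValueError("effect_size vector must have length n_causal")
    true_beta[causal_idx] = effects
    phenos = [simulate_trait(g, covariates, true_beta, spec,
                             np.random.default_rng(ss)) for ss in rep_ss]
    causal_ids = {g.snp_ids[j] for j in causal_idx}
    logger.info("simulated study: n=%d, k=%d, %d causal SNPs, %d replicate(s)",
                spec.n, spec.k, spec.n_causal, spec.n_replicates)
    return SimulatedStudy(genotypes=g, phenotypes=phenos,
                          causal_ids=causal_ids, true_beta=true_beta,
                          mafs=mafs)


KNOWN_METHODS = ("brsvd", "single_snp", "l1_external")


def _l1_pvalues(g: GenotypeMatrix, p: PhenotypeTable, J: int,
                seed: int) -> dict[str, float]:
    """External L1 (lasso) baseline wrapped in the same permutation scheme.

    The penalty is fixed once on the raw data by cross-validation; each
    permutation refits the lasso at that penalty. Off-the-shelf solver,
    not a reimplementation.
    """
    from sklearn.linear_model import Lasso, LassoCV

    from .permutation import empirical_pvalues, lambda_statistics

    X = np.column_stack([g.dosages, p.covariates])
    X = X - X.mean(axis=0)
    y = p.trait - p.trait.mean()
    cv = LassoCV(cv=5, n_alphas=20, random_state=0, max_iter=2000).fit(X, y)
    model = Lasso(alpha=cv.alpha_, max_iter=2000)
    beta_raw = model.fit(X, y).coef_[: g.n_snps]
    rng = np.random.default_rng(seed)
    deltas = np.empty((g.n_snps, J))
    for j in range(J):
        yp = rng.permutation(y)
        deltas[:, j] = beta_raw - model.fit(X, yp).coef_[: g.n_snps]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # many exact-zero lasso rows
        pv = empirical_pvalues(lambda_statistics(deltas))
    # a SNP never selected in raw or permuted fits carries no evidence
    never = (beta_raw == 0) & (deltas == 0).all(axis=1)
    pv[never] = 1.0
    return dict(zip(g.snp_ids, pv))


def run_benchmark(spec: SimulationSpec,
                  methods: tuple[str, ...] = ("brsvd", "single_snp"),
                  alpha: dict[str, float] | None = None,
                  prior: PriorSpec | None = None,
                  J: int = 200,
                  ) -> dict[str, dict]:
    """Run each method on every replicate and average the validity metrics.

    Default selection thresholds follow each method's convention: empirical
    p < 0.05 for the joint methods (all SNPs evaluated in one test) and the
    Bonferroni genome-wide threshold 0.05/k for the single-SNP scan.
    """
    for m in methods:
        if m not in KNOWN_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {KNOWN_METHODS}")
    alpha = alpha or {}
    study = simulate_study(spec)
    g = study.genotypes
    all_snps = g.snp_ids
    per_method: dict[str, list[ConfusionMetrics]] = {m: [] for m in methods}
    perm_seed_root = np.random.SeedSequence(spec.seed + 1).generate_state(
        spec.n_replicates) % (2**31)
    for i, pheno in enumerate(study.phenotypes):
        for m in methods:
            if m == "brsvd":
                res = run_brsvd_association(
                    g, pheno, prior=prior,
                    perm_cfg=PermutationConfig(J=J, seed=int(perm_seed_root[i])),
                    run_gibbs=False)
                sel = select_significant(res.snp_table(), alpha.get(m, 0.05))
            elif m == "single_snp":
                scan = scan_dataframe(single_snp_scan(g, pheno))
                thr = alpha.get(m, genomewide_threshold(spec.k, 0.05))
                sel = select_significant(scan, thr)
            else:  # l1_external
                pv = _l1_pvalues(g, pheno, J=J, seed=int(perm_seed_root[i]))
                sel = select_significant(pv, alpha.get(m, 0.05))
            per_method[m].append(confusion_metrics(sel, study.causal_ids, all_snps))
        logger.info("benchmark replicate %d/%d done", i + 1, spec.n_replicates)
    return {m: average_over_replicates(ms) for m, ms in per_method.items()}


def sensitivity_at_fpr(pvalues: dict[str, float], causal: set[str],
                       target_fpr: float) -> float:
    """Sensitivity when the p-value threshold is set so the empirical
    false-positive rate among non-causal SNPs does not exceed target_fpr.

    Used to compare methods at a matched operating point rather than at
    their nominal (differently calibrated) thresholds.
    """
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    n_null = sum(1 for sid in pvalues if sid not in causal)
    n_causal = len(causal & set(pvalues))
    if n_causal == 0:
        raise ValueError("no causal SNPs present in the result set")
    max_fp = int(np.floor(target_fpr * n_null))
    tp = best_tp = fp = 0
    for sid, _ in items:
        if sid in causal:
            tp += 1
        else:
            fp += 1
            if fp > max_fp:
                break
        best_tp = tp
    return best_tp / n_causal
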