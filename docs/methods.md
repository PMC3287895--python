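# Methods

## Model and reduction

The package fits the standard Gaussian linear model y = Xβ + ε,
ε ~ N(0, σ²Iₙ), where X is the n×p design holding k SNP dosage columns
(0/1/2 copies of the coded allele) followed by c covariate columns, with
p = k + c typically far larger than n. The thin singular value
decomposition X′ = A D F′ (A: p×r, F: n×r, both with orthonormal columns;
D = diag(d₁ ≥ … ≥ d_r > 0)) rewrites the model on the superfactor vector
γ = A′β:

    y = Lγ + ε,  L = F D.

Inference happens on γ (dimension r ≤ min(n, p)) and is mapped back to the
original coefficients by β = Aγ, the unique minimum-Euclidean-norm
solution of γ = A′β. Because A has orthonormal columns this map is an
isometry (‖β‖ = ‖γ‖) and reproduces γ exactly (A′β = γ); fitted values of
the reduced and full models coincide (Lγ = Xβ).

Interpretation caveat: β = Aγ is the projection of any true coefficient
vector onto the row space of X. When k ≫ n the per-SNP magnitudes are
heavily shrunk and should be read as a ranking/testing signal, not as
unbiased effect estimates.

## Conjugate posterior

Priors: β | σ² ~ N(β*, σ²·m·I_p) and σ² ~ InvGamma(shape a/2, scale b/2).
Through γ = A′β the prior on β induces γ | σ² ~ N(A′β*, σ²·m·I_r); the
shape/scale halving is chosen so each γᵢ is marginally Student-t with
exactly n + a degrees of freedom. With γ* = A′β* and L′L = D²:

    vᵢ      = 1 / (dᵢ² + 1/m)
    γ̃       = diag(v) (D F′y + γ*/m)
    a_post  = a + n                    (IG shape a_post/2)
    b_post  = b + ‖y − Lγ̃‖² + ‖γ̃ − γ*‖²/m   (IG scale b_post/2)

so γ | σ², y ~ N(γ̃, σ²·diag(v)), σ² | y ~ IG(a_post/2, b_post/2), and
marginally γᵢ ~ γ̃ᵢ + t_{n+a} · sqrt(b_post/a_post · vᵢ). The Gibbs
sampler alternates these two full conditionals (the σ² conditional given γ
has shape (a + n + r)/2 and scale (b + ‖y − Lγ‖² + ‖γ − γ*‖²/m)/2),
starting from the maximum-likelihood superfactor γ̂ = D⁻¹F′y. Because the
γ conditional's mean does not depend on σ², the chain mixes essentially in
one step.

The reported effect vector is the *analytic* posterior mean Aγ̃, not the
Monte-Carlo average of the draws: the closed form is exact, deterministic,
and is what the permutation test permutes. The Gibbs draws serve σ²
inference, credible intervals (`BRSVDResults.conf_int`) and the
distributional diagnostics.

## Permutation significance

For shuffle j of the trait, δᵢⱼ = β̂ᵢ(raw) − β̂ᵢ(shuffle j) and

    Λᵢ = mean_j(δᵢⱼ) / sd_j(δᵢⱼ),    pᵢ = 2(1 − Φ(|Λᵢ|)).

The denominator is the *sample standard deviation* across permutations,
not sd/√J: only that reading gives Λ a stable standard-normal limit as J
grows (the sd/√J variant, kept behind `lambda_statistics(..., scale="sem")`
for comparison, diverges with J under the null). Only y is permuted; X and
its SVD are fixed, so each refit is β̂(y_π) = H y_π + offset with the p×n
operator H = A diag(d·v) F′ precomputed once (or A diag(1/d) F′ for the
MLE option). Default J = 1000, making the Monte-Carlo error of Λ small
relative to the |Λ| ≈ 2 decision boundary. Degenerate rows (zero
permutation variance) yield Λ = 0 when the mean difference is also zero,
otherwise ±∞ mapped to p = 0 with a warning.

Permuting y alone also severs the trait–covariate association, so when
covariate effects are present the permutation null spread of SNP
estimates is mildly inflated and SNP p-values are slightly conservative.
The calibration guarantees below are therefore stated under the global
null (trait independent of every design column), which is also how the
null-calibration benchmark is generated.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| prior β* | 0 | prior mean of every coefficient |
| prior m | 1000 | prior variance multiplier (units of σ²); weakly informative |
| prior a, b | 1, 1 | IG hyperparameters on σ²; marginal t df = n + a |
| center | true | mean-center y and all columns of X; no intercept column, keeping the prior exchangeable across columns |
| svd rank_tol | max(n,p)·eps | relative singular-value cutoff; drops constant/duplicate-column null directions |
| gibbs | n_iter 2000, burn_in 500, thin 1 | ample for a one-step-mixing chain; ≥100 retained draws enforced |
| perm J | 1000 | permutations for Λ |
| selection α | 0.05, strict p < α | all SNPs are evaluated in one joint test, so no multiplicity correction; the single-SNP scan instead uses the Bonferroni threshold α/k |

Covariates receive the same prior as SNP columns and are carried through
the permutation machinery, but are reported separately and excluded from
SNP selection.

## Single-SNP baseline

The comparator scan regresses the trait on [intercept, covariates, one
SNP] per variant, with the Wald t test (n − c − 2 df) on the SNP
coefficient. It is computed by Frisch–Waugh residualization (project y and
all dosage columns off the intercept+covariate block once, then simple
regression per SNP), which is algebraically identical to the joint fit;
tests verify it against statsmodels OLS coefficient-by-coefficient.
An optional external L1 (lasso) arm wraps scikit-learn's solver in the
same permutation scheme; it is a packaged off-the-shelf baseline, not part
of the method.

## Synthetic data generator

The generator emulates the structure the method targets — a sequence-data
panel of mostly rare, independent biallelic SNPs with a sparse causal set
and covariate effects:

- per SNP, MAF ~ Uniform(0.005, 0.5); dosages Binomial(2, MAF)
  (Hardy–Weinberg), monomorphic columns redrawn up to 10 times;
- covariates sex ~ Bern(0.5), age ~ N(50, 10), smoking ~ Bern(0.3) with
  default trait effects (0.2, 0.05/yr, 0.2) — an age-dominated covariate
  signal;
- trait y = Gβ_true + Cb + ε, ε ~ N(0, σ²), σ = 1; causal effects default
  0.5 per allele copy on the residual-sd scale; replicate phenotypes share
  genotypes, covariates and the causal set and differ only in the noise
  stream;
- presets: desk scale (n=200, k=1000), a 697×24,487/39-causal panel-scale
  preset, and a strong-effect power preset (n=300, k=1000, 5 causal at
  β=1.5, σ=1).

What it does **not** emulate: linkage disequilibrium, population
stratification, relatedness, genotyping error, and any particular
phenotype-generating architecture beyond additivity. Passing benchmarks
therefore demonstrate correctness of the inference machinery and its
calibration under the model's own assumptions, not robustness to the
correlation structure of real panels.

In the power preset the causal SNPs are drawn among common variants
(MAF ≥ 0.05). With the effect size fixed in residual-sd units, a
MAF-0.005 site has ~3 carriers at n=300 and is undetectable by any
method; a power benchmark needs signals that are detectable in principle.
Rare variants remain in the panel and in the panel-scale preset.

## Numerical choices and edge cases

- Rank truncation uses a relative cutoff on singular values; all-zero
  designs raise instead of returning an empty factorization.
- b_post is computed from the residual form b + ‖y − Lγ̃‖² + ‖γ̃ − γ*‖²/m,
  which is algebraically equal to the textbook quadratic-form expression
  but cannot go negative under roundoff.
- Missing dosages are mean-imputed per SNP at load time (keeps n fixed and
  the matrix dense); observed entries are never modified, the mask is kept.
- Constant design columns are retained (they vanish into the discarded
  null space) but logged; constant SNPs in the single-SNP scan are flagged
  degenerate with p = 1.
- An exact single-SNP fit (zero residual) reports p = 0 rather than a
  0/0 statistic.
- Seeds: one user seed per run is expanded via `SeedSequence` into
  independent Gibbs / permutation / simulation streams, so changing J
  cannot perturb the Gibbs chain; identical seeds give byte-identical
  output files.

## Problem sizes used in the shipped benchmarks

Unit and property tests run on designs up to a few hundred samples and ~1
thousand SNPs; the calibration benchmark uses n=200, k=500, J=200 and the
power benchmark n=300, k=1000, J=200 with 1 replicate — sizes at which the
closed-form permutation operator makes the full pipeline run in seconds
while leaving the statistical claims (calibration bands, Monte-Carlo error
bounds) meaningful. The panel-scale preset (697×24,487) is provided for
users who want to exercise the full dimensionality.

## Known limitations

- Minimum-norm back-transformed effects are not comparable across designs
  with different ranks; use Λ/p-values for inference.
- The normal approximation for Λ assumes large J and exchangeability of
  the trait under the null; with strong covariate signal the SNP p-values
  are conservative (see above).
- No LD-aware inference: correlated SNPs share superfactor directions and
  their effects are smeared proportionally.
- Binary traits are out of scope (the probit analogue of this reduction
  is a separate method).
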