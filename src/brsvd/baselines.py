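"""Single-SNP linear-regression scan (the PLINK-style comparator).

Each SNP is tested one at a time by ordinary least squares of the trait on
[intercept, covariates, SNP dosage]; the Wald t statistic on the SNP
coefficient (n - c - 2 residual degrees of freedom) gives a two-sided
p-value. The scan is computed by Frisch-Waugh residualization — trait and
dosages are projected off the intercept+covariate block once, then each
SNP is a simple regression on residuals — which is algebraically identical
to the per-SNP joint OLS fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, PhenotypeTable

__all__ = ["ScanResult", "single_snp_scan", "scan_dataframe",
           "genomewide_threshold", "PLINK_OPERATIONAL_CUTOFF"]

#: operational genome-wide cutoff commonly used as an approximate
#: Bonferroni level for ~0.05 over tens of thousands of SNPs
PLINK_OPERATIONAL_CUTOFF = 1e-5


@dataclass
class ScanResult:
    snp_id: str
    beta: float
    se: float  # nan when degenerate
    tstat: float
    pvalue: float
    n_used: int
    degenerate: bool = False


def single_snp_scan(g: GenotypeMatrix, p: PhenotypeTable) -> list[ScanResult]:
    """OLS scan of the trait on each SNP with covariate adjustment.

    Constant SNPs (or SNPs collinear with the covariates) are degenerate:
    se is NaN and the p-value is 1. A singular covariate block raises.
    """
    if g.sample_ids != p.sample_ids:
        raise ValueError("inputs are not sample-aligned; call align_samples first")
    n, c = g.n_samples, p.n_covariates
    df_resid = n - c - 2
    if df_resid < 1:
        raise ValueError(f"n={n} too small for c={c} covariates (need n > c + 2)")
    Z = np.column_stack([np.ones(n), p.covariates])
    rank_z = np.linalg.matrix_rank(Z)
    if rank_z < Z.shape[1]:
        raise ValueError("covariate block is singular (collinear covariates)")
    # residualize trait and dosages off [1 | covariates]
    Q, _ = np.linalg.qr(Z)
    y_res = p.trait - Q @ (Q.T @ p.trait)
    G_res = g.dosages - Q @ (Q.T @ g.dosages)

    sxx = np.einsum("ij,ij->j", G_res, G_res)
    sxy = G_res.T @ y_res
    syy = float(y_res @ y_res)
    ok = sxx > max(np.max(sxx), 1.0) * np.finfo(float).eps * n

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, sxy / sxx, 0.0)
        rss = syy - beta**2 * sxx
        rss = np.maximum(rss, 0.0)
        se = np.where(ok, np.sqrt(rss / df_resid / sxx), np.nan)
        # exact fit (rss = 0): t diverges, p -> 0
        tstat = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    pval = np.where(np.isinf(tstat), 0.0, pval)

    out = []
    for j, sid in enumerate(g.snp_ids):
        degen = not ok[j]
        out.append(ScanResult(
            snp_id=sid,
            beta=float(beta[j]) if not degen else 0.0,
            se=float(se[j]),
            tstat=float(tstat[j]) if not degen else 0.0,
            pvalue=float(pval[j]) if not degen else 1.0,
            n_used=n,
            degenerate=bool(degen),
        ))
    return out


def scan_dataframe(results: list[ScanResult], chrom=None, pos=None) -> pd.DataFrame:
    df = pd.DataFrame({
        "snp_id": [r.snp_id for r in results],
        "beta": [r.beta for r in results],
        "tstat": [r.tstat for r in results],
        "p_value": [r.pvalue for r in results],
        "degenerate": [r.degenerate for r in results],
    })
    if chrom is not None:
        df.insert(1, "chrom", list(chrom))
    if pos is not None:
        df.insert(2 if chrom is not None else 1, "pos", list(pos))
    return df


def genomewide_threshold(k: int, alpha: float = 0.05) -> float:
    """Bonferroni per-test threshold alpha / k for k SNPs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / k
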