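"""Readers and writers for genotype/phenotype data and association results.

Genotypes arrive as additive dosages (0/1/2 copies of the coded allele) from
one of three dialects: PLINK ``.raw`` (``--recode A``), a plain TSV dosage
matrix (first column sample id, header row of SNP ids), or VCF with GT fields.
Missing calls are optionally mean-imputed per SNP so the design matrix stays
dense and the sample size fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "FormatError",
    "IdentifierError",
    "AlignmentError",
    "read_genotypes",
    "read_phenotypes",
    "align_samples",
    "write_results",
]


class FormatError(ValueError):
    """Input file does not parse in the declared dialect."""


class IdentifierError(ValueError):
    """Duplicate or inconsistent sample/SNP identifiers."""


class AlignmentError(ValueError):
    """Genotype and phenotype sample sets do not overlap."""


@dataclass
class GenotypeMatrix:
    """n x k additive dosage matrix with sample and SNP identifiers.

    ``missing_mask`` is True where the original call was missing (before any
    imputation); observed entries are never altered by imputation.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, k = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_ids) != k:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {k} columns")
        if len(set(self.sample_ids)) != n:
            raise IdentifierError("duplicate sample ids")
        if len(set(self.snp_ids)) != k:
            raise IdentifierError("duplicate SNP ids")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.dosages)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.dosages.shape:
                raise ValueError("missing_mask shape mismatch")
        if self.chrom is not None and len(self.chrom) != k:
            raise ValueError("chrom length mismatch")
        if self.pos is not None:
            self.pos = np.asarray(self.pos)
            if len(self.pos) != k:
                raise ValueError("pos length mismatch")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            chrom=None if self.chrom is None else list(self.chrom),
            pos=None if self.pos is None else self.pos.copy(),
            missing_mask=self.missing_mask[idx],
        )


@dataclass
class PhenotypeTable:
    """Quantitative trait and covariates for n samples, aligned by id."""

    sample_ids: list[str]
    trait: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates.reshape(len(self.trait), -1)
        n = len(self.sample_ids)
        if self.trait.shape != (n,):
            raise ValueError("trait length mismatch")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate row mismatch")
        if self.covariates.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names length mismatch")
        if np.isnan(self.trait).any():
            raise ValueError("trait contains missing values after load")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def take_samples(self, idx: Sequence[int]) -> "PhenotypeTable":
        idx = np.asarray(idx, dtype=int)
        return PhenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            trait=self.trait[idx],
            covariates=self.covariates[idx],
            covariate_names=list(self.covariate_names),
        )


def _finalize(dosages: np.ndarray, sample_ids, snp_ids, chrom, pos, impute: bool) -> GenotypeMatrix:
    """Drop all-missing columns, optionally mean-impute, build the matrix."""
    dosages = np.asarray(dosages, dtype=float)
    mask = np.isnan(dosages)
    all_missing = mask.all(axis=0)
    if all_missing.any():
        dropped = [snp_ids[j] for j in np.flatnonzero(all_missing)]
        logger.warning("dropping %d SNP column(s) with no observed calls: %s",
                       len(dropped), ", ".join(dropped[:5]))
        keep = ~all_missing
        dosages = dosages[:, keep]
        mask = mask[:, keep]
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
        if chrom is not None:
            chrom = [c for c, k in zip(chrom, keep) if k]
        if pos is not None:
            pos = np.asarray(pos)[keep]
    if impute and mask.any():
        col_means = np.nanmean(dosages, axis=0)
        fill = np.broadcast_to(col_means, dosages.shape)
        dosages = np.where(mask, fill, dosages)
    return GenotypeMatrix(dosages=dosages, sample_ids=list(sample_ids),
                          snp_ids=list(snp_ids), chrom=chrom, pos=pos,
                          missing_mask=mask)


_PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_plink_raw(path: Path, impute: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    header = list(df.columns)
    if header[: len(_PLINK_RAW_META)] != _PLINK_RAW_META:
        raise FormatError(
            f"{path}:1: expected PLINK .raw header starting "
            f"'{' '.join(_PLINK_RAW_META)}', got '{' '.join(header[:6])}'"
        )
    snp_ids = header[len(_PLINK_RAW_META):]
    sample_ids = df["IID"].tolist()
    geno = df[snp_ids].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return _finalize(geno, sample_ids, snp_ids, None, None, impute)


def _read_tsv(path: Path, impute: bool) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}:1: TSV needs a sample-id column plus >=1 SNP column")
    sample_ids = df.iloc[:, 0].tolist()
    snp_ids = list(df.columns[1:])
    geno = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return _finalize(geno, sample_ids, snp_ids, None, None, impute)


def _read_vcf(path: Path, impute: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multiallelic site %s:%d", var.CHROM, var.POS)
            continue
        col = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            # half-missing genotypes count as missing
            if any(a < 0 for a in alleles):
                continue
            col[i] = float(sum(1 for a in alleles if a > 0))
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        cols.append(col)
    if not cols:
        raise FormatError(f"{path}: no biallelic sites found")
    geno = np.column_stack(cols)
    return _finalize(geno, sample_ids, snp_ids, chrom, np.asarray(pos), impute)


def read_genotypes(path, format: str = "tsv", impute: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    Parameters
    ----------
    path : path-like
    format : {"plink_raw", "tsv", "vcf"}
        ``plink_raw``: header ``FID IID PAT MAT SEX PHENOTYPE`` then one
        0/1/2/NA column per SNP. ``tsv``: first column sample id, header row
        of SNP ids. ``vcf``: GT fields converted to allele-count dosages;
        multiallelic sites are skipped; half-missing genotypes are missing.
    impute : bool
        Fill missing dosages with the per-SNP mean of observed calls. With
        ``impute=False`` missing entries remain NaN but are flagged in
        ``missing_mask`` either way.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"plink_raw": _read_plink_raw, "tsv": _read_tsv, "vcf": _read_vcf}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown genotype format {format!r}; choose from {sorted(readers)}")
    g = reader(path, impute)
    logger.info("read genotypes: n=%d samples, k=%d SNPs (%s)", g.n_samples, g.n_snps, format)
    return g


def read_phenotypes(path, trait_name: str, covariate_names: Sequence[str] = (),
                    sample_col: str | None = None) -> PhenotypeTable:
    """Read a phenotype/covariate TSV; drop samples with a missing trait."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if sample_col is None:
        sample_col = df.columns[0]
    for col in [trait_name, *covariate_names]:
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path} (have {list(df.columns)})")
    trait = pd.to_numeric(df[trait_name], errors="coerce")
    keep = trait.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d sample(s) with missing trait %r", n_dropped, trait_name)
    df = df.loc[keep]
    if df.empty:
        raise ValueError(f"no usable samples: every row of {path} lacks trait {trait_name!r}")
    cov = df[list(covariate_names)].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float) \
        if covariate_names else np.empty((len(df), 0))
    return PhenotypeTable(
        sample_ids=df[sample_col].astype(str).tolist(),
        trait=trait.loc[keep].to_numpy(dtype=float),
        covariates=cov,
        covariate_names=list(covariate_names),
    )


def align_samples(g: GenotypeMatrix, p: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both inputs to shared samples, in genotype-file order."""
    pheno_index = {s: i for i, s in enumerate(p.sample_ids)}
    g_idx = [i for i, s in enumerate(g.sample_ids) if s in pheno_index]
    if not g_idx:
        raise AlignmentError("no samples shared between genotypes and phenotypes")
    p_idx = [pheno_index[g.sample_ids[i]] for i in g_idx]
    if g_idx == list(range(g.n_samples)) and p_idx == list(range(p.n_samples)):
        return g, p
    return g.take_samples(g_idx), p.take_samples(p_idx)


def write_results(path, table: pd.DataFrame) -> None:
    """Write per-SNP association rows as TSV.

    Columns ``snp_id``, ``beta``, ``p_value`` are required plus either
    ``lambda`` or ``tstat`` for the statistic; ``chrom``/``pos`` optional
    (written as '.') . Floats carry 8 significant digits so a round-trip
    read reproduces them well within 1e-6 relative.
    """
    df = pd.DataFrame(table).copy()
    stat_col = "lambda" if "lambda" in df.columns else "tstat"
    required = ["snp_id", "beta", stat_col, "p_value"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"results table missing column {col!r}")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            df[col] = "."
    out = df[["snp_id", "chrom", "pos", "beta", stat_col, "p_value"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.8g", na_rep=".")
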