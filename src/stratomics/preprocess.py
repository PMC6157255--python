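"""Quality control, genotype imputation, outlier flagging, and phenotype derivation.

QC mirrors a family-study complete-case protocol: minor-allele-frequency
filtering at 0.01, stochastic imputation of missing genotypes from each
SNP's empirical genotype distribution, and a PCA-score surrogate for
outlier detection.  The drug response is the binary indicator that mean
post-treatment triglycerides fell more than 30% below the mean
pre-treatment level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import InvalidConfigError
from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ResponseVector:
    """Derived drug response: change = (post - pre)/pre, response = change < cutoff."""

    sample_ids: np.ndarray
    tg_pre: np.ndarray
    tg_post: np.ndarray
    change: np.ndarray
    response: np.ndarray  # int {0,1}


@dataclass
class QCReport:
    snps_removed_maf: int = 0
    genotypes_imputed: int = 0
    outliers_flagged: list | None = None
    samples_retained: int = 0


def snp_maf(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency from non-missing dosages."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G.dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def maf_filter(G: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop SNPs with MAF < threshold (computed on non-missing calls)."""
    if not (0.0 <= threshold <= 0.5):
        raise InvalidConfigError("MAF threshold must lie in [0, 0.5]")
    if G.n_snps == 0:
        return G
    maf = snp_maf(G)
    keep = maf >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("maf_filter: removed %d/%d SNPs below MAF %g",
                    removed, G.n_snps, threshold)
    return G.select_snps(keep)


def impute_missing(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Sample each missing call from that SNP's empirical {0,1,2} distribution.

    Observed calls are preserved bit-exactly; a SNP with no observed call is
    an error.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    dos = G.dosages.copy()
    miss = np.isnan(dos)
    n_missing = int(miss.sum())
    for j in np.where(miss.any(axis=0))[0]:
        obs = dos[~miss[:, j], j]
        if obs.size == 0:
            raise ValueError(f"SNP {G.snp_ids[j]} has no observed genotype to impute from")
        counts = np.array([(obs == k).sum() for k in (0.0, 1.0, 2.0)], dtype=float)
        dos[miss[:, j], j] = rng.choice([0.0, 1.0, 2.0], size=int(miss[:, j].sum()),
                                        p=counts / counts.sum())
    if n_missing:
        logger.info("impute_missing: imputed %d genotype calls", n_missing)
    out = G.select_snps(slice(None))
    out.dosages = dos
    return out


def pca_outliers(X: np.ndarray, n_pcs: int = 10, sd_mult: float = 6.0) -> np.ndarray:
    """Indices of samples extreme on any top principal component.

    The column-standardized matrix is decomposed once; a sample is flagged
    when its score on any of the leading ``n_pcs`` components exceeds
    ``sd_mult`` times that component's score SD.  Constant columns are
    dropped with a warning before the decomposition.
    """
    if n_pcs < 1:
        raise InvalidConfigError("n_pcs must be >= 1")
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        logger.warning("pca_outliers: dropping %d constant columns", int(const.sum()))
        X, sd = X[:, ~const], sd[~const]
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    Z = (X - X.mean(axis=0)) / sd
    k = min(n_pcs, min(Z.shape) - 1)
    if k < 1:
        raise InvalidConfigError("n_pcs must be smaller than min(matrix dimensions)")
    # scores = U * S from the thin SVD; only the leading k needed
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * S[:k]
    score_sd = scores.std(axis=0, ddof=0)
    score_sd[score_sd == 0] = 1.0
    flagged = (np.abs(scores) > sd_mult * score_sd).any(axis=1)
    return np.where(flagged)[0]


def derive_response(tg: pd.DataFrame, cutoff: float = -0.30) -> ResponseVector:
    """Binary fenofibrate response from the four TG visits.

    tg_pre is the mean of visits 1-2 (pre-treatment), tg_post of visits 3-4;
    change = (post - pre)/pre and response = 1 iff change < cutoff (strict:
    "reduced by more than 30%").
    """
    vals = tg[["tg_v1", "tg_v2", "tg_v3", "tg_v4"]].to_numpy(dtype=float)
    if (vals <= 0).any() or np.isnan(vals).any():
        raise ValueError("all four TG visits must be present and strictly positive")
    pre = vals[:, :2].mean(axis=1)
    post = vals[:, 2:].mean(axis=1)
    change = (post - pre) / pre
    return ResponseVector(tg["sample_id"].to_numpy(object), pre, post, change,
                          (change < cutoff).astype(int))


@dataclass
class Standardizer:
    """Per-column z-score transform fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd == 0, 1.0, self.sd)
        Z = (np.asarray(X, dtype=float) - self.mean) / sd
        Z[:, self.sd == 0] = 0.0
        return Z


def standardize_features(X: np.ndarray, fit_rows: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Z-score columns using mean/SD from ``fit_rows`` only (no leakage).

    Zero-SD columns map to 0.  Returns the transformed full matrix and the
    fitted transform for later application to held-out rows.
    """
    X = np.asarray(X, dtype=float)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.dtype == bool:
        fit = X[fit_rows]
    else:
        fit = X[np.asarray(fit_rows, dtype=int)]
    if fit.shape[0] == 0:
        raise ValueError("fit_rows must be nonempty")
    tf = Standardizer(fit.mean(axis=0), fit.std(axis=0, ddof=0))
    return tf.transform(X), tf


def run_qc(cohort, maf_threshold: float = 0.01, seed: int = 0,
           n_pcs: int = 10, sd_mult: float = 6.0, flag_outliers: bool = True):
    """Full QC pass: MAF filter -> imputation -> outlier flag -> re-filter.

    Outliers are flagged on both the genotype and methylation matrices and
    the flags unioned; if samples drop, the MAF filter is re-run on the
    reduced cohort.  Returns (clean cohort, QCReport).
    """
    report = QCReport(outliers_flagged=[])
    n_before = cohort.genotypes.n_snps
    geno = maf_filter(cohort.genotypes, maf_threshold)
    report.snps_removed_maf = n_before - geno.n_snps
    report.genotypes_imputed = int(np.isnan(geno.dosages).sum())
    geno = impute_missing(geno, seed)
    cohort = _with_genotypes(cohort, geno)

    if flag_outliers:
        flags = set(pca_outliers(geno.dosages, n_pcs, sd_mult))
        flags |= set(pca_outliers(cohort.methylation.betas, n_pcs, sd_mult))
        if flags:
            report.outliers_flagged = sorted(cohort.sample_ids[sorted(flags)])
            keep = np.setdiff1d(np.arange(cohort.n_samples), sorted(flags))
            cohort = cohort.subset(keep)
            geno2 = maf_filter(cohort.genotypes, maf_threshold)
            report.snps_removed_maf += cohort.genotypes.n_snps - geno2.n_snps
            cohort = _with_genotypes(cohort, geno2)
    report.samples_retained = cohort.n_samples
    return cohort, report


def _with_genotypes(cohort, geno):
    from .datatypes import Cohort
    return Cohort(genotypes=geno, methylation=cohort.methylation,
                  covariates=cohort.covariates, tg=cohort.tg,
                  families=cohort.families, truth=cohort.truth)
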