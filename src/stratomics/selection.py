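"""Family-adjusted per-marker screening.

SNPs are screened by GEE marginal logistic regression (exchangeable working
correlation, robust Wald test); CpG sites by the kinship LMM with variance
components held at the null fit.  Markers pass at the study's screening
threshold p < 1e-4 (strict).  Scans are univariate: one marker plus an
intercept, with optional covariate adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, KinshipMatrix, MethylationMatrix
from .gee import GEELogistic, _ClusterIndex
from .lmm import KinshipLMM

P_THRESHOLD = 1e-4


@dataclass
class SelectionResult:
    """Per-marker effect estimates, Wald statistics, p-values, selection."""

    marker_ids: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    chromosomes: np.ndarray | None = None
    positions: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "marker_id": self.marker_ids,
            "chr": self.chromosomes if self.chromosomes is not None else "NA",
            "pos": self.positions if self.positions is not None else -1,
            "beta": self.beta, "se": self.se, "stat": self.stat,
            "p": self.p, "selected": self.selected.astype(int),
        })
        return df


def gee_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    clusters,
    covariates: np.ndarray | None = None,
    threshold: float = P_THRESHOLD,
) -> SelectionResult:
    """GEE logistic scan of every SNP against the binary response.

    Requires imputed, MAF-filtered genotypes.  Per-marker fit failures are
    recorded as missing p (never selected) and do not abort the scan.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(G.dosages).any():
        raise ValueError("gee_scan requires imputed genotypes")
    index = _ClusterIndex(clusters)
    n = len(y)
    extra = (np.atleast_2d(np.asarray(covariates, dtype=float))
             if covariates is not None else np.empty((n, 0)))
    m = G.n_snps
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    stat = np.zeros(m)
    pvals = np.full(m, np.nan)
    ones = np.ones((n, 1))
    for j in range(m):
        X = np.column_stack([ones, G.dosages[:, j:j + 1], extra])
        res = GEELogistic(y, X, index).fit()
        if res.converged and not res.separation and np.isfinite(res.bse[1]):
            beta[j] = res.params[1]
            se[j] = res.bse[1]
            stat[j] = res.zvalues[1]
            pvals[j] = res.pvalues[1]
    with np.errstate(invalid="ignore"):
        selected = pvals < threshold
    selected = np.where(np.isnan(pvals), False, selected)
    return SelectionResult(G.snp_ids, beta, se, stat, pvals, selected,
                           G.chromosomes, G.positions)


def lmm_scan(
    y: np.ndarray,
    M: MethylationMatrix,
    K: KinshipMatrix,
    covariates: np.ndarray | None = None,
    threshold: float = P_THRESHOLD,
) -> SelectionResult:
    """Kinship-LMM scan of every CpG site's beta values against the response.

    The null model (intercept + optional covariates, kinship random effect)
    is fitted once by REML; each site is then tested by GLS in the rotated
    space with the variance ratio held at the null fit.  Constant sites get
    p = 1 and effect 0.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, np.atleast_2d(np.asarray(covariates, dtype=float))])
    null = KinshipLMM(y, K, W).fit()
    beta, se, stat, pvals = null.scan_markers(M.betas)
    selected = pvals < threshold
    return SelectionResult(M.cpg_ids, beta, se, stat, pvals, selected,
                           M.chromosomes, M.positions)


def select_markers(res: SelectionResult, threshold: float = P_THRESHOLD) -> list:
    """Marker ids with p < threshold, ascending p, ties broken by marker id."""
    with np.errstate(invalid="ignore"):
        mask = res.p < threshold
    mask = np.where(np.isnan(res.p), False, mask)
    chosen = sorted(zip(res.p[mask], res.marker_ids[mask]),
                    key=lambda t: (t[0], str(t[1])))
    return [mid for _, mid in chosen]
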