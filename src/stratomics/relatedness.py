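"""LD pruning and empirical kinship (GRM) estimation.

Pruning greedily scans each chromosome left to right, retaining a SNP only
if its squared dosage correlation with every already-retained SNP inside
the base-pair window stays below the threshold (default r-squared 0.2).
The kinship matrix is the VanRaden-style genomic relationship matrix from
the pruned SNPs: centered dosages scaled by the ratio-of-sums of
2 p (1 - p), so unrelateds average ~0, the diagonal ~1, and full siblings
~0.5 off-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import InvalidConfigError
from .datatypes import GenotypeMatrix, KinshipMatrix


@dataclass
class PruneConfig:
    ld_threshold: float = 0.2   # squared-correlation threshold
    window_bp: int = 500_000
    window_step: int = 1        # scan step in SNPs

    def __post_init__(self) -> None:
        if not (0.0 < self.ld_threshold <= 1.0):
            raise InvalidConfigError("ld_threshold must lie in (0, 1]")
        if self.window_bp <= 0 or self.window_step <= 0:
            raise InvalidConfigError("window_bp and window_step must be positive")


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (0 if either constant)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    if np.isnan(g1).any() or np.isnan(g2).any():
        raise ValueError("dosage vectors must be imputed (no missing values)")
    s1, s2 = g1.std(), g2.std()
    if s1 == 0 or s2 == 0:
        return 0.0
    r = np.mean((g1 - g1.mean()) * (g2 - g2.mean())) / (s1 * s2)
    return float(r * r)


def ld_prune(G: GenotypeMatrix, cfg: PruneConfig | None = None) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns the retained snp_ids.

    Requires SNPs sorted by (chromosome, position) and no missing dosages.
    A SNP is retained iff its r2 with every already-retained SNP within
    ``window_bp`` upstream is below ``ld_threshold`` (ties go to the
    earlier SNP).  Deterministic.
    """
    cfg = cfg or PruneConfig()
    if np.isnan(G.dosages).any():
        raise ValueError("ld_prune requires imputed genotypes")
    for c in pd.unique(G.chromosomes):
        pos = G.positions[G.chromosomes == c]
        if (np.diff(pos) < 0).any():
            raise ValueError("SNPs must be sorted by (chromosome, position)")

    retained: list[int] = []
    # center columns once; r2 via cached norms
    D = G.dosages - G.dosages.mean(axis=0)
    norms = np.sqrt((D * D).sum(axis=0))
    for c in pd.unique(G.chromosomes):
        idx = np.where(G.chromosomes == c)[0]
        kept_here: list[int] = []
        for j in idx:
            ok = True
            for k in reversed(kept_here):
                if G.positions[j] - G.positions[k] > cfg.window_bp:
                    break
                if norms[j] == 0 or norms[k] == 0:
                    continue
                r = float(D[:, j] @ D[:, k]) / (norms[j] * norms[k])
                if r * r >= cfg.ld_threshold:
                    ok = False
                    break
            if ok:
                kept_here.append(j)
        retained.extend(kept_here)
    return G.snp_ids[np.sort(retained)]


def kinship_grm(G_pruned: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from imputed, pruned dosages.

    K = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix centered
    by 2 p_j; monomorphic SNPs are excluded from both Z and the scale sum.
    Negative eigenvalues are clipped at zero for downstream use.
    """
    X = G_pruned.dosages
    if np.isnan(X).any():
        raise ValueError("kinship_grm requires imputed genotypes")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("kinship_grm needs at least 2 polymorphic SNPs")
    Xp, pp = X[:, poly], p[poly]
    Z = Xp - 2.0 * pp
    scale = 2.0 * np.sum(pp * (1.0 - pp))
    K = (Z @ Z.T) / scale
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, G_pruned.sample_ids).clipped_psd()


def write_kinship(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.sample_ids,
                 columns=K.sample_ids).to_csv(path, sep="\t", float_format="%.10g")


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(df.to_numpy(dtype=float), df.columns.to_numpy(object))
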