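"""Generalized estimating equations for a binary outcome in family clusters.

Marginal logistic regression with an exchangeable working correlation and a
robust (sandwich) covariance, the standard family-study device for testing
per-SNP association while absorbing within-sibship outcome correlation.
Coefficients are updated by Fisher scoring alternated with a moment update
of the working correlation parameter alpha; the exchangeable working
inverse is applied in closed form per cluster, so each iteration is O(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm

_SEPARATION_BOUND = 15.0


@dataclass
class GEEResults:
    """Fit results: coefficients, sandwich covariance, working correlation."""

    params: np.ndarray
    cov_robust: np.ndarray
    working_alpha: float
    n_clusters: int
    converged: bool
    iterations: int
    separation: bool = False
    names: list = field(default_factory=list)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        if not self.converged or self.separation:
            return np.full_like(self.params, np.nan)
        return 2.0 * norm.sf(np.abs(self.zvalues))

    def summary(self) -> str:
        names = self.names or [f"x{i}" for i in range(len(self.params))]
        lines = [
            "GEE logistic (exchangeable working correlation, sandwich SE)",
            f"clusters: {self.n_clusters}   alpha-hat: {self.working_alpha:.4f}   "
            f"converged: {self.converged} ({self.iterations} iter)",
            f"{'term':>12} {'coef':>10} {'robust se':>10} {'z':>8} {'P>|z|':>10}",
        ]
        for nm, b, s, z, p in zip(names, self.params, self.bse, self.zvalues,
                                  self.pvalues):
            lines.append(f"{nm:>12} {b:>10.4f} {s:>10.4f} {z:>8.3f} {p:>10.3e}")
        return "\n".join(lines)


class _ClusterIndex:
    """Sorted cluster layout enabling reduceat-based per-cluster sums."""

    def __init__(self, clusters):
        codes, inverse = np.unique(np.asarray(clusters, dtype=object),
                                   return_inverse=True)
        self.order = np.argsort(inverse, kind="stable")
        sorted_codes = inverse[self.order]
        self.starts = np.searchsorted(sorted_codes, np.arange(len(codes)))
        self.sizes = np.diff(np.append(self.starts, len(inverse)))
        self.expand = np.repeat(np.arange(len(codes)), self.sizes)  # cluster of each sorted row
        self.n_clusters = len(codes)
        self.n_pairs = float((self.sizes * (self.sizes - 1)).sum() / 2.0)
        self.max_size = int(self.sizes.max())

    def cluster_sum(self, Z: np.ndarray) -> np.ndarray:
        """Per-cluster column sums of a sorted (n x p) array."""
        return np.add.reduceat(Z, self.starts, axis=0)


class GEELogistic:
    """GEE marginal logistic model for clustered binary data.

    Parameters
    ----------
    endog : 0/1 response vector.
    exog : design matrix (include the intercept column explicitly).
    clusters : family identifier per sample.
    """

    def __init__(self, endog, exog, clusters, names=None):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("endog/exog row mismatch")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        if isinstance(clusters, _ClusterIndex):
            self.index = clusters
        else:
            if len(self.y) != len(clusters):
                raise ValueError("clusters must have one entry per sample")
            self.index = _ClusterIndex(clusters)
        self.names = list(names) if names is not None else []

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> GEEResults:
        ci = self.index
        ys = self.y[ci.order]
        Xs = self.X[ci.order]
        n, p = Xs.shape
        beta = np.zeros(p)
        alpha = 0.0
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            eta = Xs @ beta
            mu = expit(eta)
            a = np.clip(mu * (1.0 - mu), 1e-10, None)
            sqa = np.sqrt(a)
            resid = (ys - mu) / sqa  # Pearson residuals

            # moment update of alpha (with dof corrections) before the beta step
            phi = float(resid @ resid) / max(n - p, 1)
            if ci.n_pairs > p:
                csum = ci.cluster_sum(resid[:, None])[:, 0]
                pair_sum = float(((csum ** 2).sum() - resid @ resid) / 2.0)
                alpha = pair_sum / (phi * (ci.n_pairs - p))
                lo = -1.0 / (ci.max_size - 1) + 1e-6 if ci.max_size > 1 else 0.0
                alpha = float(np.clip(alpha, lo, 1.0 - 1e-6))
            else:
                alpha = 0.0

            # exchangeable working inverse applied in closed form
            shrink = (alpha / (1.0 + (ci.sizes - 1) * alpha))[ci.expand]
            Xt = Xs * sqa[:, None]          # D = A X, whitened by A^{1/2}
            s = resid
            RinvX = (Xt - shrink[:, None] * ci.cluster_sum(Xt)[ci.expand]) / (1.0 - alpha)
            Rinvs = (s - shrink * ci.cluster_sum(s[:, None])[ci.expand, 0]) / (1.0 - alpha)
            B = Xt.T @ RinvX
            u = Xt.T @ Rinvs
            try:
                step = np.linalg.solve(B, u)
            except np.linalg.LinAlgError:
                break
            beta_new = beta + step
            denom = max(float(np.abs(beta).max()), 1.0)
            beta = beta_new
            if float(np.abs(step).max()) / denom < tol:
                converged = True
                break

        separation = bool(np.abs(beta).max() > _SEPARATION_BOUND)

        # sandwich covariance at the final estimate
        eta = Xs @ beta
        mu = expit(eta)
        a = np.clip(mu * (1.0 - mu), 1e-10, None)
        sqa = np.sqrt(a)
        s = (ys - mu) / sqa
        shrink = (alpha / (1.0 + (ci.sizes - 1) * alpha))[ci.expand]
        Xt = Xs * sqa[:, None]
        RinvX = (Xt - shrink[:, None] * ci.cluster_sum(Xt)[ci.expand]) / (1.0 - alpha)
        Rinvs = (s - shrink * ci.cluster_sum(s[:, None])[ci.expand, 0]) / (1.0 - alpha)
        B = Xt.T @ RinvX
        g = ci.cluster_sum(Xt * Rinvs[:, None])  # per-cluster score contributions
        M = g.T @ g
        try:
            Binv = np.linalg.inv(B)
            cov = Binv @ M @ Binv
            cov = (cov + cov.T) / 2.0
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            converged = False
        return GEEResults(beta, cov, float(alpha), ci.n_clusters, converged, it,
                          separation, self.names)
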