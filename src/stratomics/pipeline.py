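"""Stepwise multi-omics prediction pipeline with family-blocked cross-validation.

Evaluates four nested predictor sets in the study's fixed order — a
random-SNP baseline, screened SNPs, screened SNPs + screened CpGs, and all
of those plus clinical covariates — by 5-fold cross-validation in which
whole families stay within one fold and marker screening is re-run inside
each fold on training samples only, so held-out samples never influence
feature choice.  Consecutive models are compared by the exact Wilcoxon
rank-sum test on their fold test errors.
"""

from __future__ import annotations

import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm, rankdata

from .ann import TrainConfig, error_rate, forward, init_ann, predict_class, train
from .datatypes import Cohort, FamilyStructure, GenotypeMatrix, KinshipMatrix
from .preprocess import derive_response, standardize_features
from .relatedness import PruneConfig, kinship_grm, ld_prune
from .selection import gee_scan, lmm_scan, select_markers

logger = logging.getLogger(__name__)

MODEL_ORDER = ("baseline", "snp", "snp+cpg", "snp+cpg+clinical")


@dataclass
class PipelineConfig:
    k: int = 5
    p_threshold: float = 1e-4
    ld_threshold: float = 0.2
    ld_window_bp: int = 500_000
    maf_threshold: float = 0.01
    n_hidden: int = 10
    baseline_n: int = 100
    ann_epochs: int = 600
    seed: int = 0
    select_once: bool = False        # screen on all samples (leaky; for comparison)
    folds_ignore_family: bool = False
    adjust_covariates: bool = False  # covariate-adjusted screening


@dataclass
class FoldAssignment:
    fold_index: np.ndarray  # per-sample fold in {1..k}
    k: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_index == fold


@dataclass
class CVReport:
    model_label: str
    train_errors: list
    test_errors: list
    n_features: list
    feature_ids: list

    @property
    def mean_test_error(self) -> float:
        return float(np.mean(self.test_errors))

    @property
    def sd_test_error(self) -> float:
        return float(np.std(self.test_errors, ddof=1))

    @property
    def mean_train_error(self) -> float:
        return float(np.mean(self.train_errors))

    @property
    def sd_train_error(self) -> float:
        return float(np.std(self.train_errors, ddof=1))

    def to_dict(self) -> dict:
        return {
            "model": self.model_label,
            "train_errors": [float(e) for e in self.train_errors],
            "test_errors": [float(e) for e in self.test_errors],
            "mean_train_error": self.mean_train_error,
            "sd_train_error": self.sd_train_error,
            "mean_test_error": self.mean_test_error,
            "sd_test_error": self.sd_test_error,
            "n_features": [int(n) for n in self.n_features],
            "feature_ids": [list(map(str, f)) for f in self.feature_ids],
        }


@dataclass
class StepwiseReport:
    reports: list                     # CVReport in MODEL_ORDER
    wilcoxon_p: dict = field(default_factory=dict)  # consecutive-pair p-values

    def to_dict(self) -> dict:
        return {"models": [r.to_dict() for r in self.reports],
                "wilcoxon_p": {k: float(v) for k, v in self.wilcoxon_p.items()}}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def plot(self, ax=None):
        """Mean test error (+/- SD over folds) against the predictor steps."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        means = [100 * r.mean_test_error for r in self.reports]
        sds = [100 * r.sd_test_error for r in self.reports]
        x = np.arange(len(self.reports))
        ax.errorbar(x, means, yerr=sds, marker="o", capsize=4)
        ax.set_xticks(x)
        ax.set_xticklabels([r.model_label for r in self.reports], rotation=20)
        ax.set_ylabel("5-fold CV test error (%)")
        ax.set_xlabel("predictor set")
        return ax

    def summary(self) -> str:
        lines = [f"{'model':>18} {'train err':>16} {'test err':>16} {'features':>9}"]
        for r in self.reports:
            nf = int(np.mean(r.n_features))
            lines.append(
                f"{r.model_label:>18} "
                f"{100 * r.mean_train_error:6.2f}% ± {100 * r.sd_train_error:5.2f}% "
                f"{100 * r.mean_test_error:6.2f}% ± {100 * r.sd_test_error:5.2f}% "
                f"{nf:>9}")
        for pair, p in self.wilcoxon_p.items():
            lines.append(f"Wilcoxon rank-sum {pair}: p = {p:.4f}")
        return "\n".join(lines)


def family_folds(fam: FamilyStructure, k: int = 5, seed: int = 0,
                 ignore_family: bool = False) -> FoldAssignment:
    """Assign families to k folds, balancing sample counts greedily.

    Largest family first into the currently smallest fold with a seeded
    random tie-break; all members of one family share a fold.  With
    ``ignore_family`` samples are assigned individually (leaky; provided
    for comparison only).
    """
    rng = np.random.default_rng(seed)
    n = fam.n_samples
    if ignore_family:
        units = [(1, i) for i in range(n)]
        unit_members = {i: [i] for i in range(n)}
    else:
        fam_codes, inv = np.unique(fam.family_ids, return_inverse=True)
        if len(fam_codes) < k:
            raise ValueError(f"need at least {k} families for {k} folds")
        unit_members = {f: list(np.where(inv == f)[0]) for f in range(len(fam_codes))}
        units = [(len(m), f) for f, m in unit_members.items()]
    if len(units) < k:
        raise ValueError(f"need at least {k} units for {k} folds")
    tie = rng.permutation(len(units))
    order = sorted(range(len(units)), key=lambda i: (-units[i][0], tie[i]))
    fold_sizes = np.zeros(k)
    fold_index = np.zeros(n, dtype=int)
    for i in order:
        size, u = units[i]
        smallest = np.flatnonzero(fold_sizes == fold_sizes.min())
        f = int(rng.choice(smallest))
        fold_sizes[f] += size
        for s in unit_members[u]:
            fold_index[s] = f + 1
    return FoldAssignment(fold_index, k)


def baseline_random_features(G: GenotypeMatrix, n: int = 100, seed: int = 0) -> list:
    """n SNP ids sampled uniformly without replacement (the null baseline)."""
    if n > G.n_snps:
        raise ValueError("n exceeds the number of SNPs")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(G.n_snps, size=n, replace=False))
    return list(G.snp_ids[idx])


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p: exact enumeration for combined n <= 20.

    Mid-ranks handle ties; the exact p is twice the smaller tail
    probability of the observed tie-adjusted rank sum (capped at 1).  A
    tie-corrected normal approximation with continuity correction is used
    above combined n = 20.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    n1, n2 = len(a), len(b)
    w = float(ranks[:n1].sum())
    if n1 + n2 <= 20:
        lo = hi = 0
        total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            ws = float(ranks[list(comb)].sum())
            total += 1
            if ws <= w + 1e-9:
                lo += 1
            if ws >= w - 1e-9:
                hi += 1
        return float(min(1.0, 2.0 * min(lo, hi) / total))
    mean = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / ((n1 + n2) * (n1 + n2 - 1))
    var = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


@dataclass
class PredictorSpec:
    """Which feature blocks enter one model.

    When every block resolves to zero features in a fold (e.g. no marker
    passed screening), the model falls back to ``fallback_snps`` — the
    baseline random-SNP block — so it degrades to the baseline-only model
    rather than a bias-only network (logged).
    """

    snps: str | list | None = None   # "selected", explicit id list, or None
    cpgs: str | None = None          # "selected" or None
    clinical: bool = False
    label: str = ""
    fallback_snps: list | None = None


def _fold_selections(cohort: Cohort, response, folds: FoldAssignment,
                     K: KinshipMatrix, cfg: PipelineConfig):
    """Per-fold screened SNP and CpG ids, from training samples only."""
    covars = (cohort.covariates[["age", "sex", "smoking"]].to_numpy(float)
              if cfg.adjust_covariates else None)
    snp_sel, cpg_sel = {}, {}

    def _screen(idx):
        sub = cohort.subset(idx)
        y = response.response[idx]
        cv = covars[idx] if covars is not None else None
        gres = gee_scan(y, sub.genotypes, sub.families.family_ids, cv,
                        cfg.p_threshold)
        Ksub = KinshipMatrix(K.values[np.ix_(idx, idx)], K.sample_ids[idx])
        mres = lmm_scan(y, sub.methylation, Ksub, cv, cfg.p_threshold)
        return select_markers(gres, cfg.p_threshold), select_markers(mres, cfg.p_threshold)

    if cfg.select_once:
        all_idx = np.arange(cohort.n_samples)
        s, c = _screen(all_idx)
        for f in range(1, folds.k + 1):
            snp_sel[f], cpg_sel[f] = s, c
    else:
        for f in range(1, folds.k + 1):
            train_idx = np.where(~folds.test_mask(f))[0]
            snp_sel[f], cpg_sel[f] = _screen(train_idx)
    return snp_sel, cpg_sel


def _feature_matrix(cohort: Cohort, snp_ids, cpg_ids, clinical: bool):
    cols, names = [], []
    if snp_ids:
        lookup = {s: j for j, s in enumerate(cohort.genotypes.snp_ids)}
        idx = [lookup[s] for s in snp_ids]
        cols.append(cohort.genotypes.dosages[:, idx])
        names.extend(snp_ids)
    if cpg_ids:
        lookup = {s: j for j, s in enumerate(cohort.methylation.cpg_ids)}
        idx = [lookup[s] for s in cpg_ids]
        cols.append(cohort.methylation.betas[:, idx])
        names.extend(cpg_ids)
    if clinical:
        cols.append(cohort.covariates[["age", "sex", "smoking"]].to_numpy(float))
        names.extend(["age", "sex", "smoking"])
    if not cols:
        logger.warning("model has no features; network reduces to its bias")
        return np.zeros((cohort.n_samples, 1)), ["<none>"]
    return np.column_stack(cols), names


def cv_evaluate(cohort: Cohort, response, folds: FoldAssignment,
                predictors: PredictorSpec, cfg: PipelineConfig,
                kinship: KinshipMatrix | None = None,
                fold_selections=None) -> CVReport:
    """Cross-validated ANN evaluation of one predictor set.

    Marker screening runs inside each fold on training samples only (unless
    precomputed selections are supplied or ``cfg.select_once`` is set);
    standardization is fitted on training rows only.
    """
    y = response.response
    if fold_selections is None and (predictors.snps == "selected"
                                    or predictors.cpgs == "selected"):
        if kinship is None:
            raise ValueError("kinship needed to screen CpGs/SNPs per fold")
        fold_selections = _fold_selections(cohort, response, folds, kinship, cfg)
    snp_sel, cpg_sel = fold_selections if fold_selections else ({}, {})

    train_errors, test_errors, n_features, feat_ids = [], [], [], []
    for f in range(1, folds.k + 1):
        test = folds.test_mask(f)
        train_idx = np.where(~test)[0]
        test_idx = np.where(test)[0]
        if len(np.unique(y[test_idx])) < 2:
            logger.warning("fold %d has a single response class in test set", f)

        snp_ids = (snp_sel.get(f, []) if predictors.snps == "selected"
                   else list(predictors.snps) if predictors.snps else [])
        cpg_ids = cpg_sel.get(f, []) if predictors.cpgs == "selected" else []
        if not snp_ids and not cpg_ids and predictors.fallback_snps:
            # the stepwise chain builds on the baseline when nothing screened in
            logger.warning("fold %d: model '%s' has no screened features; "
                           "falling back to the baseline SNP block",
                           f, predictors.label)
            snp_ids = list(predictors.fallback_snps)
        X, names = _feature_matrix(cohort, snp_ids, cpg_ids, predictors.clinical)
        Xz, _ = standardize_features(X, train_idx)

        label_code = zlib.crc32(predictors.label.encode())  # stable across runs
        ann_seed = int(np.random.SeedSequence(
            (cfg.seed, f, label_code)).generate_state(1)[0] % (2 ** 31))
        tcfg = TrainConfig(max_epochs=cfg.ann_epochs, seed=ann_seed)
        model = init_ann(Xz.shape[1], cfg.n_hidden, tcfg)
        model, _ = train(model, Xz[train_idx], y[train_idx], tcfg)
        train_errors.append(error_rate(predict_class(model, Xz[train_idx]), y[train_idx]))
        test_errors.append(error_rate(predict_class(model, Xz[test_idx]), y[test_idx]))
        n_features.append(X.shape[1])
        feat_ids.append(names)
    return CVReport(predictors.label, train_errors, test_errors, n_features, feat_ids)


def stepwise_run(cohort: Cohort, cfg: PipelineConfig,
                 folds: FoldAssignment | None = None) -> StepwiseReport:
    """Run the four predictor sets in the study's fixed order.

    The cohort must already be QC'd (imputed, MAF-filtered).  LD pruning
    and the kinship matrix are computed once from the genotypes (they use
    no response information); screening is fold-local.
    """
    response = derive_response(cohort.tg)
    if folds is None:
        folds = family_folds(cohort.families, cfg.k, cfg.seed,
                             cfg.folds_ignore_family)
    pruned = ld_prune(cohort.genotypes,
                      PruneConfig(cfg.ld_threshold, cfg.ld_window_bp))
    keep = np.isin(cohort.genotypes.snp_ids, pruned)
    K = kinship_grm(cohort.genotypes.select_snps(keep))

    selections = _fold_selections(cohort, response, folds, K, cfg)
    for f in range(1, folds.k + 1):
        if not selections[0][f]:
            logger.warning("fold %d: no SNP passed screening; model runs on "
                           "remaining feature blocks", f)

    baseline_ids = baseline_random_features(cohort.genotypes, cfg.baseline_n,
                                            cfg.seed)
    specs = [
        PredictorSpec(snps=baseline_ids, label="baseline"),
        PredictorSpec(snps="selected", label="snp", fallback_snps=baseline_ids),
        PredictorSpec(snps="selected", cpgs="selected", label="snp+cpg",
                      fallback_snps=baseline_ids),
        PredictorSpec(snps="selected", cpgs="selected", clinical=True,
                      label="snp+cpg+clinical", fallback_snps=baseline_ids),
    ]
    reports = [cv_evaluate(cohort, response, folds, spec, cfg, K, selections)
               for spec in specs]
    wil = {}
    for r1, r2 in zip(reports, reports[1:]):
        wil[f"{r1.model_label} vs {r2.model_label}"] = wilcoxon_rank_sum(
            r1.test_errors, r2.test_errors)
    return StepwiseReport(reports, wil)
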