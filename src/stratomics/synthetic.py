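"""Synthetic family-cohort generator.

Emulates the structure of a fenofibrate-response family study: sibships of
2-4 full siblings, founder genotypes in Hardy-Weinberg proportions with
Mendelian transmission to siblings, CpG beta values with a within-family
variance component, clinical covariates, and four triglyceride (TG) visit
values whose derived percentage change encodes a binary drug response with
a calibrated responder rate.

Responder status is generated first on the liability (log-odds) scale so
that planted SNP/CpG/covariate effects act on the binary response exactly
as the downstream screens assume; TG visit values are then constructed to
be consistent with that status (change < -30% iff responder), with
visit-level noise that cannot flip the status.

Each generator draws from its own seeded stream derived from
``config.seed``, so components are individually reproducible and
``simulate_cohort`` is bit-identical for a fixed config.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import InvalidConfigError, SimulationConfig
from .datatypes import (
    AlignmentError,
    Cohort,
    FamilyStructure,
    GenotypeMatrix,
    MethylationMatrix,
)

# distinct per-component RNG streams derived from the config seed
_STREAM_FAMILIES = 1
_STREAM_GENOTYPES = 2
_STREAM_METHYLATION = 3
_STREAM_COVARIATES = 4
_STREAM_PHENOTYPE = 5

_N_AUTOSOMES = 22


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stream)))


def simulate_families(config: SimulationConfig) -> FamilyStructure:
    """Draw the family structure: two founders plus 2-4 siblings per family.

    Founders carry role ``founder`` and are excluded from the analysis
    cohort unless ``config.include_founders`` is set; they exist so that
    sibling genotypes can be generated by Mendelian transmission.
    """
    config.validate()
    rng = _rng(config, _STREAM_FAMILIES)
    lo, hi = config.sibs_per_family
    n_sibs = rng.integers(lo, hi + 1, size=config.n_families)
    sample_ids, family_ids, roles = [], [], []
    for f, k in enumerate(n_sibs):
        fam = f"F{f + 1:04d}"
        for parent in ("P1", "P2"):
            sample_ids.append(f"{fam}_{parent}")
            family_ids.append(fam)
            roles.append("founder")
        for s in range(int(k)):
            sample_ids.append(f"{fam}_S{s + 1}")
            family_ids.append(fam)
            roles.append("sibling")
    return FamilyStructure(np.array(sample_ids, dtype=object),
                           np.array(family_ids, dtype=object),
                           np.array(roles, dtype=object))


def analysis_samples(fam: FamilyStructure, config: SimulationConfig) -> np.ndarray:
    """Boolean mask of samples entering the analysis cohort."""
    if config.include_founders:
        return np.ones(fam.n_samples, dtype=bool)
    return fam.roles == "sibling"


def _snp_map(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic SNP ids, chromosomes, and sorted positions."""
    m = config.n_snps
    snp_ids = np.array([f"snp{j + 1:05d}" for j in range(m)], dtype=object)
    chroms = np.array([str(1 + (j * _N_AUTOSOMES) // max(m, 1)) for j in range(m)],
                      dtype=object)
    # positions increase within chromosome with seeded 1-10 kb spacing
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 99)))
    gaps = rng.integers(1_000, 10_001, size=m)
    positions = np.empty(m, dtype=np.int64)
    pos = 0
    prev_chrom = None
    for j in range(m):
        if chroms[j] != prev_chrom:
            pos = 0
            prev_chrom = chroms[j]
        pos += int(gaps[j])
        positions[j] = pos
    return snp_ids, chroms, positions


def simulate_genotypes(fam: FamilyStructure, config: SimulationConfig) -> GenotypeMatrix:
    """Simulate founder genotypes under HWE and sibling genotypes by descent.

    Per SNP, the founder alt-allele frequency is drawn uniformly from
    ``config.maf_range``; each sibling inherits one uniformly chosen allele
    from each founder, so full siblings share alleles identical by descent.
    Missing calls are inserted at ``config.missing_rate`` in the returned
    (analysis-subset) matrix.
    """
    if fam.n_samples == 0:
        raise InvalidConfigError("family structure is empty")
    rng = _rng(config, _STREAM_GENOTYPES)
    m = config.n_snps
    fam_codes, fam_index = np.unique(fam.family_ids, return_inverse=True)
    n_fam = len(fam_codes)

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    # founder alleles: (family, parent, allele, snp); int8 so dosages add
    alleles = (rng.random((n_fam, 2, 2, m)) < p).astype(np.int8)

    dosages = np.zeros((fam.n_samples, m), dtype=float)
    founder_seen: dict[tuple[int, int], int] = {}
    for i in range(fam.n_samples):
        f = fam_index[i]
        if fam.roles[i] == "founder":
            k = founder_seen.get((f, 0), 0)
            founder_seen[(f, 0)] = k + 1
            dosages[i] = alleles[f, min(k, 1)].sum(axis=0)
        else:
            pick_m = rng.integers(0, 2, size=m)
            pick_f = rng.integers(0, 2, size=m)
            dosages[i] = (alleles[f, 0, pick_m, np.arange(m)]
                          + alleles[f, 1, pick_f, np.arange(m)])

    mask = analysis_samples(fam, config)
    dosages = dosages[mask]
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    snp_ids, chroms, positions = _snp_map(config)
    return GenotypeMatrix(dosages, fam.sample_ids[mask], snp_ids, chroms, positions,
                          np.full(m, "A", dtype=object), np.full(m, "G", dtype=object))


def simulate_methylation(fam: FamilyStructure, config: SimulationConfig) -> MethylationMatrix:
    """Simulate CpG beta values with within-family correlation.

    Values are generated on the M-value (logit) scale as site mean + family
    random effect + individual noise, with the family share of the unit
    total variance equal to ``cpg_family_icc``; betas are the inverse logit.
    """
    if fam.n_samples == 0:
        raise InvalidConfigError("family structure is empty")
    config.validate()
    rng = _rng(config, _STREAM_METHYLATION)
    mask = analysis_samples(fam, config)
    fam_codes, fam_index = np.unique(fam.family_ids[mask], return_inverse=True)
    n, m = int(mask.sum()), config.n_cpgs

    site_mean = rng.normal(0.0, 1.5, size=m)
    sd_fam = np.sqrt(config.cpg_family_icc)
    sd_ind = np.sqrt(1.0 - config.cpg_family_icc)
    fam_effect = rng.normal(0.0, sd_fam, size=(len(fam_codes), m))
    mvals = site_mean + fam_effect[fam_index] + rng.normal(0.0, sd_ind, size=(n, m))
    betas = expit(mvals)

    cpg_ids = np.array([f"cg{j + 1:05d}" for j in range(m)], dtype=object)
    chroms = np.array([str(1 + (j * _N_AUTOSOMES) // max(m, 1)) for j in range(m)],
                      dtype=object)
    positions = np.arange(1, m + 1, dtype=np.int64) * 2_000
    return MethylationMatrix(betas, fam.sample_ids[mask], cpg_ids, chroms, positions)


def simulate_covariates(fam: FamilyStructure, config: SimulationConfig) -> pd.DataFrame:
    """Age (uniform 20-70 years), sex (Bernoulli 0.5), smoking (Bernoulli 0.25)."""
    rng = _rng(config, _STREAM_COVARIATES)
    mask = analysis_samples(fam, config)
    n = int(mask.sum())
    return pd.DataFrame({
        "sample_id": fam.sample_ids[mask],
        "family_id": fam.family_ids[mask],
        "age": rng.integers(20, 71, size=n),
        "sex": rng.integers(0, 2, size=n),
        "smoking": (rng.random(n) < 0.25).astype(int),
    })


def _mvalues(betas: np.ndarray) -> np.ndarray:
    return logit(np.clip(betas, 1e-12, 1 - 1e-12))


def simulate_phenotype(
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    covars: pd.DataFrame,
    fam: FamilyStructure,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate TG visit values encoding a calibrated binary drug response.

    A liability score combines causal SNP dosages (log-odds per allele),
    causal CpG M-values standardized to unit SD (log-odds per SD), clinical
    covariates, and a per-family polygenic effect.  The liability threshold
    is calibrated by root finding so the expected responder fraction equals
    ``target_response_rate``; responder status is Bernoulli in the implied
    probability.  TG visits are then built so that the derived change
    (mean(v3,v4) - mean(v1,v2)) / mean(v1,v2) is < -0.30 exactly for
    responders and >= -0.30 otherwise.

    Returns the TG visit table and a truth ledger with the causal marker
    ids, effects, and the generated response vector.
    """
    ids = list(geno.sample_ids)
    if not (ids == list(meth.sample_ids) == list(covars["sample_id"])):
        raise AlignmentError("genotypes, methylation, covariates must be sample-aligned")
    rng = _rng(config, _STREAM_PHENOTYPE)
    n = len(ids)

    causal_snps = np.sort(rng.choice(geno.n_snps, size=config.n_causal_snps,
                                     replace=False)) if config.n_causal_snps else np.array([], dtype=int)
    causal_cpgs = np.sort(rng.choice(meth.n_sites, size=config.n_causal_cpgs,
                                     replace=False)) if config.n_causal_cpgs else np.array([], dtype=int)

    lp = np.zeros(n)
    if len(causal_snps):
        d = geno.dosages[:, causal_snps]
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean, d) - col_mean  # centered; missing -> 0
        lp += d.sum(axis=1) * config.snp_effect
    if len(causal_cpgs):
        mv = _mvalues(meth.betas[:, causal_cpgs])
        sd = mv.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mv = (mv - mv.mean(axis=0)) / sd
        lp += mv.sum(axis=1) * config.cpg_effect
    b_age, b_sex, b_smoke = config.covariate_effects
    lp += (b_age * (covars["age"].to_numpy(float) - 45.0)
           + b_sex * covars["sex"].to_numpy(float)
           + b_smoke * covars["smoking"].to_numpy(float))
    if config.polygenic_sd > 0:
        fam_codes, fam_index = np.unique(covars["family_id"].to_numpy(object),
                                         return_inverse=True)
        lp += rng.normal(0.0, config.polygenic_sd, size=len(fam_codes))[fam_index]

    target = config.target_response_rate
    if np.allclose(lp, lp[0]):
        c = float(lp[0] - logit(target))
    else:
        span = float(np.abs(lp).max()) + 50.0
        c = brentq(lambda cc: expit(lp - cc).mean() - target, -span, span)
    prob = expit(lp - c)
    response = (rng.random(n) < prob).astype(int)

    tg_pre = np.exp(rng.normal(np.log(150.0), 0.35, size=n))
    change = np.where(response == 1,
                      rng.uniform(-0.60, -0.35, size=n),
                      rng.uniform(-0.25, 0.10, size=n))
    eps_pre = rng.uniform(0.0, 0.05, size=n)
    eps_post = rng.uniform(0.0, 0.05, size=n)
    tg_post = tg_pre * (1.0 + change)
    tg = pd.DataFrame({
        "sample_id": ids,
        "tg_v1": tg_pre * (1.0 + eps_pre),
        "tg_v2": tg_pre * (1.0 - eps_pre),
        "tg_v3": tg_post * (1.0 + eps_post),
        "tg_v4": tg_post * (1.0 - eps_post),
    })
    truth = {
        "causal_snps": list(geno.snp_ids[causal_snps]),
        "causal_cpgs": list(meth.cpg_ids[causal_cpgs]),
        "snp_effect": config.snp_effect,
        "cpg_effect": config.cpg_effect,
        "covariate_effects": list(config.covariate_effects),
        "liability_threshold": float(c),
        "response": response.tolist(),
    }
    return tg, truth


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Compose all generators into one aligned cohort with a truth ledger."""
    fam = simulate_families(config)
    geno = simulate_genotypes(fam, config)
    meth = simulate_methylation(fam, config)
    covars = simulate_covariates(fam, config)
    tg, truth = simulate_phenotype(geno, meth, covars, fam, config)
    mask = analysis_samples(fam, config)
    return Cohort(genotypes=geno, methylation=meth, covariates=covars, tg=tg,
                  families=fam.subset(mask), truth=truth)
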