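"""Generator contracts: family structure, Mendelian transmission, calibration."""

import numpy as np
import pytest
from scipy.special import logit

from stratomics import (
    InvalidConfigError,
    SimulationConfig,
    derive_response,
    simulate_cohort,
    simulate_families,
    simulate_genotypes,
    simulate_methylation,
)
from stratomics.synthetic import analysis_samples


def test_family_counts_and_roles():
    cfg = SimulationConfig(n_families=2, sibs_per_family=3, n_snps=5, n_cpgs=5,
                           n_causal_snps=0, n_causal_cpgs=0, seed=1)
    fam = simulate_families(cfg)
    assert (fam.roles == "founder").sum() == 4
    assert (fam.roles == "sibling").sum() == 6
    assert analysis_samples(fam, cfg).sum() == 6
    assert len(set(fam.sample_ids)) == fam.n_samples


def test_seeded_determinism_bit_identical():
    cfg = SimulationConfig(n_families=15, n_snps=60, n_cpgs=30,
                           n_causal_snps=2, n_causal_cpgs=2, seed=7)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    np.testing.assert_array_equal(a.methylation.betas, b.methylation.betas)
    assert a.tg.equals(b.tg)
    assert a.covariates.equals(b.covariates)
    assert a.truth == b.truth


@pytest.mark.parametrize("kwargs", [
    {"n_families": 0},
    {"sibs_per_family": (0, 2)},
    {"cpg_family_icc": 1.0},
    {"maf_range": (0.0, 0.5)},
    {"maf_range": (0.1, 0.6)},
    {"target_response_rate": 1.0},
    {"n_causal_snps": 50, "n_snps": 10},
    {"missing_rate": 1.0},
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(InvalidConfigError):
        SimulationConfig(**kwargs)


def test_mendelian_consistency_with_founders():
    """No sibling dosage incompatible with its two founders' genotypes."""
    cfg = SimulationConfig(n_families=30, sibs_per_family=(2, 3), n_snps=150,
                           n_cpgs=5, n_causal_snps=0, n_causal_cpgs=0,
                           missing_rate=0.0, include_founders=True, seed=11)
    fam = simulate_families(cfg)
    G = simulate_genotypes(fam, cfg)
    fam_of = dict(zip(fam.sample_ids, fam.family_ids))
    role_of = dict(zip(fam.sample_ids, fam.roles))
    by_family = {}
    for i, s in enumerate(G.sample_ids):
        by_family.setdefault(fam_of[s], {"founders": [], "sibs": []})[
            "founders" if role_of[s] == "founder" else "sibs"].append(i)
    for members in by_family.values():
        f1, f2 = (G.dosages[i] for i in members["founders"])
        lower = (f1 == 2).astype(int) + (f2 == 2).astype(int)
        upper = (f1 > 0).astype(int) + (f2 > 0).astype(int)
        for i in members["sibs"]:
            assert (G.dosages[i] >= lower).all()
            assert (G.dosages[i] <= upper).all()
        # forced heterozygotes: founders 2 x 0 transmit exactly one alt allele
        forced = (f1 == 2) & (f2 == 0) | (f1 == 0) & (f2 == 2)
        for i in members["sibs"]:
            assert (G.dosages[i][forced] == 1).all()


def test_sibling_dosage_mean_matches_maf():
    cfg = SimulationConfig(n_families=250, sibs_per_family=2, n_snps=40, n_cpgs=5,
                           n_causal_snps=0, n_causal_cpgs=0, missing_rate=0.0,
                           maf_range=(0.3, 0.3), seed=13)
    fam = simulate_families(cfg)
    G = simulate_genotypes(fam, cfg)
    # 3 SE band; sibling correlation inflates the variance of the mean by 1.5
    se = np.sqrt(2 * 0.3 * 0.7 * 1.5 / G.n_samples / G.n_snps)
    assert abs(G.dosages.mean() - 0.6) < 3 * se


def test_methylation_icc_recovered():
    """ANOVA ICC estimator on M-values recovers the configured family share."""
    cfg = SimulationConfig(n_families=150, sibs_per_family=3, n_snps=5, n_cpgs=120,
                           n_causal_snps=0, n_causal_cpgs=0, cpg_family_icc=0.5,
                           seed=17)
    fam = simulate_families(cfg)
    M = simulate_methylation(fam, cfg)
    assert (M.betas > 0).all() and (M.betas < 1).all()
    mv = logit(M.betas)
    sibs = fam.sample_ids[fam.roles == "sibling"]
    fam_codes, fidx = np.unique(
        fam.family_ids[fam.roles == "sibling"], return_inverse=True)
    k = 3
    iccs = []
    for j in range(M.n_sites):
        x = mv[:, j]
        grand = x.mean()
        group_means = np.array([x[fidx == g].mean() for g in range(len(fam_codes))])
        msb = k * ((group_means - grand) ** 2).sum() / (len(fam_codes) - 1)
        msw = sum(((x[fidx == g] - group_means[g]) ** 2).sum()
                  for g in range(len(fam_codes))) / (len(sibs) - len(fam_codes))
        iccs.append((msb - msw) / (msb + (k - 1) * msw))
    assert abs(np.mean(iccs) - 0.5) < 0.05


def test_methylation_zero_icc_uncorrelated():
    cfg = SimulationConfig(n_families=200, sibs_per_family=2, n_snps=5, n_cpgs=60,
                           n_causal_snps=0, n_causal_cpgs=0, cpg_family_icc=0.0,
                           seed=19)
    fam = simulate_families(cfg)
    M = simulate_methylation(fam, cfg)
    mv = logit(M.betas)
    # correlation of sib1 vs sib2 across families, averaged over sites
    rs = [np.corrcoef(mv[0::2, j], mv[1::2, j])[0, 1] for j in range(M.n_sites)]
    assert abs(np.mean(rs)) < 0.03


def test_responder_rate_calibration_single_cohort():
    cfg = SimulationConfig(seed=23)  # defaults: ~520 samples, target 0.576
    cohort = simulate_cohort(cfg)
    n = cohort.n_samples
    count = sum(cohort.truth["response"])
    assert abs(count - 0.576 * n) < 3 * np.sqrt(n * 0.25)


def test_responder_rate_calibration_replicates():
    """Mean responder fraction over replicates within 2 SE of the target."""
    fracs = []
    for seed in range(50):
        cfg = SimulationConfig(n_families=30, n_snps=30, n_cpgs=20,
                               n_causal_snps=2, n_causal_cpgs=2, seed=seed)
        c = simulate_cohort(cfg)
        fracs.append(np.mean(c.truth["response"]))
    n_total = 50 * 90  # ~90 sibs per replicate
    se = np.sqrt(0.576 * 0.424 / n_total)
    assert abs(np.mean(fracs) - 0.576) < 2 * se + 0.01


def test_tg_change_encodes_response_exactly():
    cfg = SimulationConfig(n_families=40, n_snps=30, n_cpgs=20,
                           n_causal_snps=2, n_causal_cpgs=2, seed=29)
    cohort = simulate_cohort(cfg)
    resp = derive_response(cohort.tg)
    np.testing.assert_array_equal(resp.response, np.array(cohort.truth["response"]))
    assert (resp.change[resp.response == 1] < -0.30).all()
    assert (resp.change[resp.response == 0] >= -0.30).all()


def test_null_config_response_constant_probability():
    """With all effects zero the liability is flat: status is pure chance."""
    cfg = SimulationConfig(n_families=100, n_snps=50, n_cpgs=30,
                           n_causal_snps=0, n_causal_cpgs=0, snp_effect=0.0,
                           cpg_effect=0.0, covariate_effects=(0, 0, 0),
                           polygenic_sd=0.0, seed=31)
    cohort = simulate_cohort(cfg)
    y = np.array(cohort.truth["response"])
    # association with any covariate should be at chance level
    for col in ("age", "sex", "smoking"):
        r = np.corrcoef(y, cohort.covariates[col].to_numpy(float))[0, 1]
        assert abs(r) < 4 / np.sqrt(len(y))
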