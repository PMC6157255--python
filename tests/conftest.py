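import numpy as np
import pytest

from stratomics import SimulationConfig, simulate_cohort
from stratomics.datatypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic family cohort with planted effects."""
    cfg = SimulationConfig(n_families=40, n_snps=150, n_cpgs=80,
                           n_causal_snps=2, n_causal_cpgs=2,
                           missing_rate=0.02, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Family-structured cohort with no planted effects anywhere."""
    cfg = SimulationConfig(n_families=60, n_snps=200, n_cpgs=150,
                           n_causal_snps=0, n_causal_cpgs=0,
                           snp_effect=0.0, cpg_effect=0.0,
                           covariate_effects=(0.0, 0.0, 0.0),
                           polygenic_sd=0.5, cpg_family_icc=0.4,
                           missing_rate=0.0, seed=202)
    return simulate_cohort(cfg)


def make_genotypes(dosages, positions=None, chromosomes=None, sample_prefix="s"):
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if chromosomes is None:
        chromosomes = np.full(m, "1", dtype=object)
    return GenotypeMatrix(
        dosages,
        np.array([f"{sample_prefix}{i}" for i in range(n)], dtype=object),
        np.array([f"v{j}" for j in range(m)], dtype=object),
        np.asarray(chromosomes, dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.full(m, "A", dtype=object),
        np.full(m, "G", dtype=object),
    )
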