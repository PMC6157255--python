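"""Core data containers shared across the pipeline.

All multi-sample containers carry an ordered ``sample_ids`` sequence; a
:class:`Cohort` guarantees that every component is indexed by the identical
ordered list.  Genotype dosages are additive alt-allele counts stored as
float arrays with ``nan`` marking missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Raised when components of a cohort do not share one sample list."""


@dataclass
class FamilyStructure:
    """Sample-to-family assignment with founder/sibling roles."""

    sample_ids: np.ndarray  # str array, unique, ordered
    family_ids: np.ndarray  # str array, one per sample
    roles: np.ndarray       # 'founder' or 'sibling' per sample

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("sample_ids must be unique")
        if not (len(self.sample_ids) == len(self.family_ids) == len(self.roles)):
            raise ValueError("sample_ids, family_ids, roles must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: np.ndarray) -> "FamilyStructure":
        return FamilyStructure(self.sample_ids[idx], self.family_ids[idx], self.roles[idx])


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with variant metadata.

    ``dosages`` holds values in {0, 1, 2} or ``nan`` for missing; rows follow
    ``sample_ids`` and columns follow ``snp_ids``.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("dosage shape inconsistent with ids")
        if len(self.snp_ids) != len(set(self.snp_ids)):
            raise ValueError("snp_ids must be unique")
        if m and (self.positions <= 0).any():
            raise ValueError("positions must be positive (1-based)")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def select_snps(self, mask_or_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, mask_or_idx],
            self.sample_ids,
            self.snp_ids[mask_or_idx],
            self.chromosomes[mask_or_idx],
            self.positions[mask_or_idx],
            self.ref[mask_or_idx],
            self.alt[mask_or_idx],
        )

    def select_samples(self, idx) -> "GenotypeMatrix":
        return replace(self, dosages=self.dosages[idx], sample_ids=self.sample_ids[idx])


@dataclass
class MethylationMatrix:
    """Samples x CpG-sites beta-value matrix (values in [0, 1])."""

    betas: np.ndarray
    sample_ids: np.ndarray
    cpg_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.cpg_ids = np.asarray(self.cpg_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.betas.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValueError("beta shape inconsistent with ids")
        if len(self.cpg_ids) != len(set(self.cpg_ids)):
            raise ValueError("cpg_ids must be unique")
        if self.betas.size and ((self.betas < 0) | (self.betas > 1)).any():
            bad = np.argwhere((self.betas < 0) | (self.betas > 1))[0]
            raise ValueError(
                f"beta outside [0,1] at sample {self.sample_ids[bad[0]]}, "
                f"site {self.cpg_ids[bad[1]]}"
            )

    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]

    @property
    def n_sites(self) -> int:
        return self.betas.shape[1]

    def select_samples(self, idx) -> "MethylationMatrix":
        return replace(self, betas=self.betas[idx], sample_ids=self.sample_ids[idx])


# Covariates and TG visits are plain DataFrames with fixed schemas; thin
# validators keep load-time contracts in one place.

COVARIATE_COLUMNS = ("sample_id", "family_id", "age", "sex", "smoking")
TG_COLUMNS = ("sample_id", "tg_v1", "tg_v2", "tg_v3", "tg_v4")


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a covariate table: required columns, no missing, binary codes."""
    missing_cols = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"covariate table missing columns: {sorted(missing_cols)}")
    df = df.loc[:, list(COVARIATE_COLUMNS)].copy()
    if df.isna().any().any():
        raise ValueError("covariate table contains missing values")
    for col in ("sex", "smoking"):
        if not df[col].isin((0, 1)).all():
            raise ValueError(f"{col} must be coded 0/1")
    return df.reset_index(drop=True)


def validate_tg(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a TG-visit table: four positive visit values per sample.

    Samples with any missing visit are dropped (flagged for exclusion), in
    line with the complete-case rule of the study design.
    """
    missing_cols = set(TG_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"TG table missing columns: {sorted(missing_cols)}")
    df = df.loc[:, list(TG_COLUMNS)].copy()
    complete = df[["tg_v1", "tg_v2", "tg_v3", "tg_v4"]].notna().all(axis=1)
    df = df.loc[complete]
    vals = df[["tg_v1", "tg_v2", "tg_v3", "tg_v4"]].to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("TG concentrations must be strictly positive")
    return df.reset_index(drop=True)


@dataclass
class Cohort:
    """Aligned bundle of all per-sample data for one analysis set."""

    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    covariates: pd.DataFrame
    tg: pd.DataFrame
    families: FamilyStructure
    truth: dict | None = field(default=None)  # causal-marker ledger from simulation

    def __post_init__(self) -> None:
        ids = list(self.families.sample_ids)
        for name, other in (
            ("genotypes", list(self.genotypes.sample_ids)),
            ("methylation", list(self.methylation.sample_ids)),
            ("covariates", list(self.covariates["sample_id"])),
            ("tg", list(self.tg["sample_id"])),
        ):
            if other != ids:
                raise AlignmentError(f"{name} sample order differs from family structure")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.families.sample_ids

    @property
    def n_samples(self) -> int:
        return self.families.n_samples

    def subset(self, idx: np.ndarray) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            genotypes=self.genotypes.select_samples(idx),
            methylation=self.methylation.select_samples(idx),
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
            tg=self.tg.iloc[idx].reset_index(drop=True),
            families=self.families.subset(idx),
            truth=self.truth,
        )


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix over samples (diagonal near 1)."""

    values: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        if (np.diag(self.values) < 0).any():
            raise ValueError("kinship diagonal must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def clipped_psd(self) -> "KinshipMatrix":
        """Return a copy with negative eigenvalues clipped at zero."""
        w, v = np.linalg.eigh(self.values)
        if w.min() >= -1e-8 and w.min() >= 0:
            return self
        w = np.clip(w, 0.0, None)
        vals = (v * w) @ v.T
        vals = (vals + vals.T) / 2.0
        return KinshipMatrix(vals, self.sample_ids)
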