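"""Simulation configuration: defaults calibrated to the study cohort.

The default configuration reproduces the structure of the real family cohort
the analysis is designed for: ~523 siblings from sibships of 2-4, a binary
fenofibrate response with a 57.6% responder rate, SNP dosages with founder
Hardy-Weinberg genotypes and Mendelian transmission, and CpG beta values
with within-family correlation.  Marker counts are desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml


class InvalidConfigError(ValueError):
    """Raised when a simulation or analysis configuration is inconsistent."""


@dataclass
class SimulationConfig:
    n_families: int = 174
    sibs_per_family: Tuple[int, int] = (2, 4)  # inclusive range, or (k, k) for fixed k
    n_snps: int = 2000
    n_cpgs: int = 1000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_causal_snps: int = 4
    n_causal_cpgs: int = 4
    snp_effect: float = 1.2          # log-odds per alt allele
    cpg_effect: float = 1.0          # log-odds per SD of M-value
    covariate_effects: Tuple[float, float, float] = (0.05, 1.2, 1.5)  # age/yr, sex, smoking
    polygenic_sd: float = 0.5        # liability SD of the per-family polygenic component
    cpg_family_icc: float = 0.3      # intraclass correlation of M-values within family
    target_response_rate: float = 0.576
    missing_rate: float = 0.02       # genotype missingness
    include_founders: bool = False   # founders simulated for transmission only by default
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sibs_per_family, int):
            self.sibs_per_family = (self.sibs_per_family, self.sibs_per_family)
        self.sibs_per_family = tuple(self.sibs_per_family)  # type: ignore[assignment]
        self.maf_range = tuple(self.maf_range)  # type: ignore[assignment]
        self.covariate_effects = tuple(self.covariate_effects)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.n_families <= 0:
            raise InvalidConfigError("n_families must be positive")
        lo, hi = self.sibs_per_family
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("sibs_per_family must be a positive count or range")
        if self.n_snps < 0 or self.n_cpgs < 0:
            raise InvalidConfigError("marker counts must be non-negative")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.n_causal_snps > self.n_snps:
            raise InvalidConfigError("n_causal_snps exceeds n_snps")
        if self.n_causal_cpgs > self.n_cpgs:
            raise InvalidConfigError("n_causal_cpgs exceeds n_cpgs")
        if not (0 <= self.cpg_family_icc < 1):
            raise InvalidConfigError("cpg_family_icc must be in [0, 1)")
        if not (0 < self.target_response_rate < 1):
            raise InvalidConfigError("target_response_rate must be in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.polygenic_sd < 0:
            raise InvalidConfigError("polygenic_sd must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
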