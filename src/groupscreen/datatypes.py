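"""Core data containers shared across the pipeline.

Omics matrices are sample-by-feature with per-feature genomic
coordinates (1-based, inclusive).  Genotypes are minor-allele counts in
{0, 1, 2} with ``-1`` marking a missing call; methylation values are
beta proportions strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING_GENOTYPE = -1


def _as_str_array(x) -> np.ndarray:
    return np.asarray(x, dtype=object)


@dataclass
class GenotypeMatrix:
    """Minor-allele counts for n samples at m SNPs."""

    values: np.ndarray  # (n, m) integer, entries in {0,1,2} or -1 (missing)
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # base-pair positions, positive integers
    maf: np.ndarray  # per-SNP minor-allele frequency in (0, 0.5]
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.snp_ids = _as_str_array(self.snp_ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        self.sample_ids = _as_str_array(self.sample_ids)
        n, m = self.values.shape
        if not (
            len(self.snp_ids) == len(self.chrom) == len(self.pos) == len(self.maf) == m
        ):
            raise ValueError("per-SNP metadata length does not match matrix width")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix height")
        ok = np.isin(self.values, (0, 1, 2, MISSING_GENOTYPE))
        if not ok.all():
            bad = np.unique(self.values[~ok])
            raise ValueError(f"genotype entries outside {{0,1,2,missing}}: {bad}")
        if (self.pos <= 0).any():
            raise ValueError("positions must be strictly positive")
        if ((self.maf <= 0) | (self.maf > 0.5)).any():
            raise ValueError("minor-allele frequencies must lie in (0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class MethylationMatrix:
    """Methylation beta values for n samples at m CpG sites."""

    values: np.ndarray  # (n, m) real, strictly inside (0, 1)
    cpg_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cpg_ids = _as_str_array(self.cpg_ids)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = _as_str_array(self.sample_ids)
        n, m = self.values.shape
        if not (len(self.cpg_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("per-CpG metadata length does not match matrix width")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix height")
        if not ((self.values > 0) & (self.values < 1)).all():
            raise ValueError("beta values must lie strictly inside (0, 1)")
        if (self.pos <= 0).any():
            raise ValueError("positions must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeTable:
    """Outcome (log mean fasting triglyceride) and covariates per sample."""

    sample_ids: np.ndarray
    outcome: np.ndarray
    age: np.ndarray
    smoking: np.ndarray  # binary

    def __post_init__(self) -> None:
        self.sample_ids = _as_str_array(self.sample_ids)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.smoking = np.asarray(self.smoking, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.outcome) == len(self.age) == len(self.smoking) == n):
            raise ValueError("phenotype columns have unequal lengths")
        if not np.isfinite(self.outcome).all():
            raise ValueError("outcome contains non-finite values")
        if not np.isin(self.smoking, (0, 1)).all():
            raise ValueError("smoking must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class GroundTruth:
    """Sparse generating model behind a synthetic phenotype.

    ``cpg_effects`` maps CpG column index -> coefficient on the logit
    (M-value) scale.  ``snp_effects`` maps SNP column index -> per-level
    effects (heterozygote, homozygote-minor) relative to the g=0
    reference.  ``interaction_effects`` maps (CpG, SNP) index pairs to
    per-level products of the logit-methylation with the genotype-level
    indicators.  Strong hierarchy is enforced: an interaction pair must
    have both of its main effects present.
    """

    cpg_effects: dict = field(default_factory=dict)
    snp_effects: dict = field(default_factory=dict)
    interaction_effects: dict = field(default_factory=dict)
    age_effect: float = 0.0
    smoking_effect: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for (jc, js) in self.interaction_effects:
            if jc not in self.cpg_effects or js not in self.snp_effects:
                raise ValueError(
                    f"interaction ({jc},{js}) violates strong hierarchy: "
                    "both main effects must be present"
                )
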