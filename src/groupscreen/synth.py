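"""Synthetic cohort generator with known sparse ground truth.

Emulates a lipid-methylation cohort: Hardy--Weinberg genotypes at drawn
minor-allele frequencies, logit-normal methylation with latent low-rank
structure (so principal-component adjustment is meaningful), genomic
positions on a single chromosome (so the interaction colocation filter
has pairs to find), and a continuous outcome -- log mean fasting
triglyceride -- that is sparse-linear in logit-methylation, genotype
level indicators, covariates and a few strong-hierarchy interaction
terms plus Gaussian noise.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .datatypes import (
    MISSING_GENOTYPE,
    GenotypeMatrix,
    GroundTruth,
    MethylationMatrix,
    PhenotypeTable,
)

__all__ = [
    "generate_genotypes",
    "generate_methylation",
    "generate_phenotype",
    "simulate_dataset",
    "write_feature_matrix",
    "write_feature_meta",
    "write_phenotype",
    "write_ground_truth",
]


def _sample_ids(n: int) -> np.ndarray:
    return np.array([f"S{i:06d}" for i in range(n)], dtype=object)


def _distinct_positions(m: int, pos_range: tuple[int, int], rng) -> np.ndarray:
    lo, hi = int(pos_range[0]), int(pos_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid pos_range {pos_range}")
    if hi - lo + 1 < m:
        raise ValueError(f"pos_range {pos_range} too narrow for {m} distinct positions")
    if hi - lo + 1 <= 4 * m:  # small range: sample without replacement directly
        pos = rng.choice(np.arange(lo, hi + 1), size=m, replace=False)
        return np.sort(pos)
    pos = np.unique(rng.integers(lo, hi + 1, size=2 * m))
    while len(pos) < m:  # pragma: no cover - vanishing probability for wide ranges
        pos = np.unique(np.concatenate([pos, rng.integers(lo, hi + 1, size=2 * m)]))
    return np.sort(rng.choice(pos, size=m, replace=False))


def generate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    chrom: str = "chr11",
    pos_range: tuple[int, int] = (1, 2_000_000),
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Independent Hardy--Weinberg genotypes.

    Each SNP draws a minor-allele frequency f uniformly from
    ``maf_range`` and genotypes g ~ Binomial(2, f), i.e.
    P(g = 0, 1, 2) = ((1-f)^2, 2f(1-f), f^2).
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie inside (0, 0.5], got {maf_range}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=m)
    values = rng.binomial(2, maf[None, :], size=(n, m)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(size=(n, m)) < missing_rate
        values = np.where(mask, np.int8(MISSING_GENOTYPE), values)
    pos = _distinct_positions(m, pos_range, rng)
    return GenotypeMatrix(
        values=values,
        snp_ids=np.array([f"rs{i:06d}" for i in range(m)], dtype=object),
        chrom=np.repeat(np.array([chrom], dtype=object), m),
        pos=pos,
        maf=maf,
        sample_ids=_sample_ids(n),
    )


def generate_methylation(
    n: int,
    m: int,
    latent_rank: int = 4,
    latent_sd: float = 0.5,
    base_sd: float = 0.8,
    mean_range: tuple[float, float] = (-2.5, 2.5),
    chrom: str = "chr11",
    pos_range: tuple[int, int] = (1, 2_000_000),
    seed: int = 0,
) -> MethylationMatrix:
    """Logit-normal methylation with ``latent_rank`` shared factors.

    On the logit scale each entry is
    ``mu_j + sum_k loadings[k, j] * z[i, k] + noise`` with z ~ N(0, 1),
    loadings ~ N(0, latent_sd^2) and noise ~ N(0, base_sd^2); the beta
    value is the inverse logit, hence strictly inside (0, 1).  The logit
    transform used downstream is therefore exactly linearizing.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if latent_rank < 0:
        raise ValueError("latent_rank must be >= 0")
    if latent_sd < 0 or base_sd < 0:
        raise ValueError("latent_sd and base_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mu = rng.uniform(mean_range[0], mean_range[1], size=m)
    m_values = np.tile(mu, (n, 1))
    if latent_rank > 0 and latent_sd > 0:
        z = rng.standard_normal(size=(n, latent_rank))
        loadings = rng.normal(0.0, latent_sd, size=(latent_rank, m))
        m_values = m_values + z @ loadings
    m_values = m_values + rng.normal(0.0, base_sd, size=(n, m))
    return MethylationMatrix(
        values=expit(m_values),
        cpg_ids=np.array([f"cg{i:08d}" for i in range(m)], dtype=object),
        chrom=np.repeat(np.array([chrom], dtype=object), m),
        pos=_distinct_positions(m, pos_range, rng),
        sample_ids=_sample_ids(n),
    )


def generate_phenotype(
    meth: MethylationMatrix,
    geno: GenotypeMatrix,
    truth: GroundTruth,
    age_range: tuple[float, float] = (20.0, 70.0),
    smoking_rate: float = 0.25,
) -> PhenotypeTable:
    """Outcome linear in logit-methylation, SNP indicators and interactions.

    Covariates (age, smoking) are drawn here, independent of the omics
    features, and returned alongside the outcome.  Missing genotype
    calls contribute through the reference level (both indicators zero).
    """
    n = meth.n_samples
    if geno.n_samples != n:
        raise ValueError("methylation and genotype sample counts differ")
    for j in truth.cpg_effects:
        if not (0 <= j < meth.n_cpgs):
            raise ValueError(f"causal CpG index {j} out of bounds")
    for j in truth.snp_effects:
        if not (0 <= j < geno.n_snps):
            raise ValueError(f"causal SNP index {j} out of bounds")
    rng = np.random.default_rng(truth.seed)
    age = rng.uniform(age_range[0], age_range[1], size=n)
    smoking = (rng.random(n) < smoking_rate).astype(float)

    y = np.full(n, float(truth.intercept))
    mvals = logit(meth.values)  # exact: beta strictly inside (0,1)
    for j, b in truth.cpg_effects.items():
        y += b * mvals[:, j]
    for j, (b1, b2) in truth.snp_effects.items():
        g = geno.values[:, j]
        y += b1 * (g == 1) + b2 * (g == 2)
    for (jc, js), (c1, c2) in truth.interaction_effects.items():
        g = geno.values[:, js]
        y += mvals[:, jc] * (c1 * (g == 1) + c2 * (g == 2))
    y += truth.age_effect * age + truth.smoking_effect * smoking
    if truth.noise_sd > 0:
        y += rng.normal(0.0, truth.noise_sd, size=n)
    return PhenotypeTable(
        sample_ids=meth.sample_ids.copy(), outcome=y, age=age, smoking=smoking
    )


def simulate_dataset(
    n: int = 500,
    m_cpg: int = 2000,
    m_snp: int = 0,
    n_causal_cpg: int = 3,
    n_causal_snp: int = 0,
    n_interactions: int = 0,
    cpg_effect: float = 0.5,
    snp_effect: tuple[float, float] = (0.3, 0.6),
    interaction_effect: float = 0.5,
    age_effect: float = 0.02,
    smoking_effect: float = 0.3,
    intercept: float = 4.0,
    noise_sd: float = 1.0,
    chrom: str = "chr11",
    chrom_length: int = 2_000_000,
    colocation_fraction: float = 1e-4,
    latent_rank: int = 4,
    latent_sd: float = 0.5,
    seed: int = 0,
):
    """One aligned synthetic cohort: methylation, genotypes, phenotype, truth.

    Causal features are drawn at random among the simulated columns;
    causal interactions are drawn among pairs that fall inside the
    colocation window, so the interaction workflow can find them, and
    their main effects are added to the supports (strong hierarchy).
    Returns ``(meth, geno, pheno, truth)``; ``geno`` is None when
    ``m_snp`` is zero.
    """
    from .design import colocated_pairs  # deferred: design depends on datatypes only

    ss = np.random.SeedSequence(seed)
    s_meth, s_geno, s_truth, s_pick = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    meth = generate_methylation(
        n, m_cpg, latent_rank=latent_rank, latent_sd=latent_sd,
        chrom=chrom, pos_range=(1, chrom_length), seed=s_meth,
    )
    geno = None
    if m_snp > 0:
        geno = generate_genotypes(
            n, m_snp, chrom=chrom, pos_range=(1, chrom_length), seed=s_geno
        )
    rng = np.random.default_rng(s_pick)

    cpg_idx = rng.choice(m_cpg, size=n_causal_cpg, replace=False) if n_causal_cpg else np.array([], int)
    cpg_effects = {int(j): float(cpg_effect) * (1 if k % 2 == 0 else -1) for k, j in enumerate(cpg_idx)}
    snp_effects: dict = {}
    interaction_effects: dict = {}
    if geno is not None and n_causal_snp:
        snp_idx = rng.choice(m_snp, size=n_causal_snp, replace=False)
        snp_effects = {int(j): (float(snp_effect[0]), float(snp_effect[1])) for j in snp_idx}
    if geno is not None and n_interactions:
        pairs = colocated_pairs(
            meth.pos, geno.pos, chrom_length, colocation_fraction,
            cpg_chrom=meth.chrom, snp_chrom=geno.chrom,
        )
        if len(pairs) < n_interactions:
            raise ValueError(
                f"only {len(pairs)} colocated pairs available for "
                f"{n_interactions} causal interactions"
            )
        chosen = rng.choice(len(pairs), size=n_interactions, replace=False)
        for k in chosen:
            jc, js = (int(v) for v in pairs[k])
            interaction_effects[(jc, js)] = (float(interaction_effect), float(2 * interaction_effect))
            # strong hierarchy: both main effects enter the model
            cpg_effects.setdefault(jc, float(cpg_effect))
            snp_effects.setdefault(js, (float(snp_effect[0]), float(snp_effect[1])))
    truth = GroundTruth(
        cpg_effects=cpg_effects,
        snp_effects=snp_effects,
        interaction_effects=interaction_effects,
        age_effect=age_effect,
        smoking_effect=smoking_effect,
        intercept=intercept,
        noise_sd=noise_sd,
        seed=s_truth,
    )
    pheno = generate_phenotype(meth, geno if geno is not None else _empty_geno(meth), truth)
    return meth, geno, pheno, truth


def _empty_geno(meth: MethylationMatrix) -> GenotypeMatrix:
    """Zero-SNP genotype matrix aligned with ``meth`` (EWAS-only cohorts)."""
    n = meth.n_samples
    return GenotypeMatrix(
        values=np.zeros((n, 0), dtype=np.int8),
        snp_ids=np.array([], dtype=object),
        chrom=np.array([], dtype=object),
        pos=np.array([], dtype=np.int64),
        maf=np.array([], dtype=float),
        sample_ids=meth.sample_ids.copy(),
    )


# ---------------------------------------------------------------------------
# TSV writers (the pipeline's file dialects)

def write_feature_matrix(path, sample_ids, feature_ids, values) -> None:
    """Rows = samples; first column ``sample_id``, then one column per feature."""
    import pandas as pd

    df = pd.DataFrame(np.asarray(values), columns=list(feature_ids))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)


def write_feature_meta(path, feature_ids, chrom, pos) -> None:
    import pandas as pd

    pd.DataFrame(
        {"feature_id": list(feature_ids), "chrom": list(chrom), "pos": np.asarray(pos)}
    ).to_csv(path, sep="\t", index=False)


def write_phenotype(path, pheno: PhenotypeTable) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": list(pheno.sample_ids),
            "outcome": pheno.outcome,
            "age": pheno.age,
            "smoking": pheno.smoking.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_ground_truth(path, truth: GroundTruth, cpg_ids=None, snp_ids=None) -> None:
    """JSON sidecar with feature identifiers and effect sizes."""
    d = asdict(truth)
    if cpg_ids is not None:
        d["cpg_effects"] = {str(cpg_ids[j]): b for j, b in truth.cpg_effects.items()}
    if snp_ids is not None:
        d["snp_effects"] = {str(snp_ids[j]): list(b) for j, b in truth.snp_effects.items()}
    if cpg_ids is not None and snp_ids is not None:
        d["interaction_effects"] = {
            f"{cpg_ids[jc]}|{snp_ids[js]}": list(c)
            for (jc, js), c in truth.interaction_effects.items()
        }
    else:
        d["interaction_effects"] = {
            f"{jc}|{js}": list(c) for (jc, js), c in truth.interaction_effects.items()
        }
    Path(path).write_text(json.dumps(d, indent=2))
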