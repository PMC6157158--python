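"""Grouped, penalized design construction.

Turns raw omics matrices into the design the screening regression runs
on: logit-transformed methylation (M-values), categorical or
linear-allele-effect genotype coding, unpenalized covariates including
principal-component scores, and -- for the interaction screen --
overlapped strong-hierarchy groups pairing each colocated CpG/SNP pair
into a five-column block [M, 1{g=1}, 1{g=2}, M*1{g=1}, M*1{g=2}].

Column bookkeeping: every design column belongs to exactly one group;
overlap between groups exists only at the source-feature level and is
recorded in ``duplication_map`` so a feature's total effect can be
recovered by summing the coefficients of all its copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    MISSING_GENOTYPE,
    GenotypeMatrix,
    MethylationMatrix,
    PhenotypeTable,
)

__all__ = [
    "Group",
    "GroupedDesign",
    "logit_mvalue",
    "impute_mode",
    "recode_minor_allele",
    "encode_snp_general",
    "encode_snp_lae",
    "colocated_pairs",
    "build_interaction_group",
    "compute_pc_scores",
    "assemble_design",
    "read_feature_matrix",
    "read_feature_meta",
    "read_phenotype",
    "load_methylation",
    "load_genotypes",
]

MODES = ("ewas", "gwas_general", "gwas_lae", "interaction")


def logit_mvalue(beta, eps: float = 1e-6):
    """M-value: log(b / (1 - b)) with b clipped to [eps, 1 - eps].

    Beta values of exactly 0 or 1 occur in array data; the clip keeps
    the transform finite while remaining monotone non-decreasing.
    """
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    b = np.asarray(beta, dtype=float)
    if ((b < 0) | (b > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, eps, 1.0 - eps)
    out = np.log(b / (1.0 - b))
    return float(out) if np.isscalar(beta) else out


def impute_mode(g: np.ndarray) -> np.ndarray:
    """Replace missing genotype calls with the per-vector modal genotype."""
    g = np.asarray(g)
    miss = g == MISSING_GENOTYPE
    if not miss.any():
        return g
    observed = g[~miss]
    if observed.size == 0:
        return np.zeros_like(g)
    counts = np.bincount(observed, minlength=3)
    return np.where(miss, np.argmax(counts), g)


def recode_minor_allele(g: np.ndarray) -> tuple[np.ndarray, bool]:
    """Orient the counted allele to be the minor one in this sample.

    Returns the (possibly flipped, g -> 2-g) vector and a flag saying
    whether a flip happened.  Missing entries stay missing.
    """
    g = np.asarray(g)
    miss = g == MISSING_GENOTYPE
    obs = g[~miss]
    if obs.size and obs.mean() / 2.0 > 0.5:
        return np.where(miss, g, 2 - g), True
    return g, False


def _check_genotype_entries(g: np.ndarray) -> None:
    if not np.isin(g, (0, 1, 2, MISSING_GENOTYPE)).all():
        raise ValueError("genotype entries must be in {0, 1, 2} or missing")


def encode_snp_general(g: np.ndarray) -> np.ndarray:
    """Indicator coding: columns 1{g==1} and 1{g==2}, reference g=0.

    The two columns are meant to be one selection group.  Missing calls
    are imputed to the modal genotype first.
    """
    g = np.asarray(g)
    _check_genotype_entries(g)
    g = impute_mode(g)
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def encode_snp_lae(g: np.ndarray) -> np.ndarray:
    """Linear-allele-effect coding: the minor-allele count as one column."""
    g = np.asarray(g)
    _check_genotype_entries(g)
    return impute_mode(g).astype(float)


def colocated_pairs(
    cpg_pos,
    snp_pos,
    chrom_length: int,
    fraction: float,
    cpg_chrom=None,
    snp_chrom=None,
) -> list[tuple[int, int]]:
    """(CpG, SNP) index pairs closer than ``fraction * chrom_length``.

    The distance cut is strict (< not <=) and pairs must share a
    chromosome label when labels are given.  Output is ordered by CpG
    position, then SNP position.
    """
    cpg_pos = np.asarray(cpg_pos, dtype=np.int64)
    snp_pos = np.asarray(snp_pos, dtype=np.int64)
    if fraction <= 0:
        raise ValueError(f"fraction must be > 0, got {fraction}")
    if (cpg_pos <= 0).any() or (snp_pos <= 0).any():
        raise ValueError("positions must be strictly positive")
    max_pos = max(cpg_pos.max(initial=0), snp_pos.max(initial=0))
    if chrom_length < max_pos:
        raise ValueError(
            f"chrom_length {chrom_length} smaller than max position {max_pos}"
        )
    window = fraction * chrom_length
    cpg_chrom = None if cpg_chrom is None else np.asarray(cpg_chrom, dtype=object)
    snp_chrom = None if snp_chrom is None else np.asarray(snp_chrom, dtype=object)

    snp_order = np.argsort(snp_pos, kind="stable")
    sp = snp_pos[snp_order]
    pairs: list[tuple[int, int]] = []
    for jc in np.argsort(cpg_pos, kind="stable"):
        # strict window: |pos_c - pos_s| < window
        lo = np.searchsorted(sp, cpg_pos[jc] - window, side="right")
        hi = np.searchsorted(sp, cpg_pos[jc] + window, side="left")
        for js in snp_order[lo:hi]:
            if abs(int(cpg_pos[jc]) - int(snp_pos[js])) >= window:
                continue  # boundary ties excluded by the strict cut
            if cpg_chrom is not None and snp_chrom is not None:
                if cpg_chrom[jc] != snp_chrom[js]:
                    continue
            pairs.append((int(jc), int(js)))
    return pairs


def build_interaction_group(cpg_col: np.ndarray, snp_cols: np.ndarray) -> np.ndarray:
    """Five-column strong-hierarchy block [M, I1, I2, M*I1, M*I2]."""
    cpg_col = np.asarray(cpg_col, dtype=float).ravel()
    snp_cols = np.asarray(snp_cols, dtype=float)
    if snp_cols.ndim != 2 or snp_cols.shape[1] != 2:
        raise ValueError("snp_cols must be an (n, 2) indicator matrix")
    if snp_cols.shape[0] != cpg_col.shape[0]:
        raise ValueError("row counts of cpg_col and snp_cols differ")
    return np.column_stack(
        [
            cpg_col,
            snp_cols[:, 0],
            snp_cols[:, 1],
            cpg_col * snp_cols[:, 0],
            cpg_col * snp_cols[:, 1],
        ]
    )


def compute_pc_scores(M: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the column-centered matrix.

    Scores are ordered by decreasing explained variance, have zero mean,
    and a deterministic sign convention (the loading entry of largest
    magnitude is positive).
    """
    M = np.asarray(M, dtype=float)
    n, m = M.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    Mc = M - M.mean(axis=0)
    u, s, vt = np.linalg.svd(Mc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        warnings.warn(
            f"requested {k} PCs but rank is {rank}; returning {rank}", stacklevel=2
        )
        k = rank
    # sign convention for reproducibility
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]
    return u[:, :k] * s[:k]


@dataclass
class Group:
    """One selection unit: a contiguous block of design columns."""

    gid: str
    start: int
    end: int  # exclusive
    weight: float  # group-LASSO penalty weight; 0 marks unpenalized
    kind: str  # covariate | cpg | snp | interaction
    feature: tuple = ()  # source feature indices (kind-dependent)
    pos: int = 0  # representative genomic position (reporting)

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def cols(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    @property
    def penalized(self) -> bool:
        return self.weight > 0


@dataclass
class GroupedDesign:
    """Design matrix plus group structure for one penalized regression."""

    X: np.ndarray
    y: np.ndarray
    groups: list
    duplication_map: dict = field(default_factory=dict)  # col -> source key
    column_meta: list = field(default_factory=list)  # per-column kind tag
    scales: np.ndarray | None = None  # divisor applied per column (1 = untouched)
    centers: np.ndarray | None = None
    y_mean: float = 0.0
    sample_ids: np.ndarray | None = None
    mode: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        p = self.X.shape[1]
        covered = np.zeros(p, dtype=bool)
        for g in self.groups:
            if g.start < 0 or g.end > p or g.start >= g.end:
                raise ValueError(f"group {g.gid} has invalid column span")
            if covered[g.start : g.end].any():
                raise ValueError(f"group {g.gid} overlaps another group's columns")
            covered[g.start : g.end] = True
        if not covered.all():
            raise ValueError("groups do not partition the design columns")
        if self.scales is None:
            self.scales = np.ones(p)
        if self.centers is None:
            self.centers = np.zeros(p)
        if not self.column_meta:
            self.column_meta = ["" for _ in range(p)]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def penalized_groups(self) -> list:
        return [g for g in self.groups if g.penalized]

    def subset_rows(self, rows: np.ndarray) -> "GroupedDesign":
        """Same structure on a row subset (used by CV and subsampling)."""
        return GroupedDesign(
            X=self.X[rows],
            y=self.y[rows],
            groups=self.groups,
            duplication_map=self.duplication_map,
            column_meta=self.column_meta,
            scales=self.scales,
            centers=self.centers,
            y_mean=self.y_mean,
            sample_ids=None if self.sample_ids is None else self.sample_ids[rows],
            mode=self.mode,
        )


def _align_samples(pheno: PhenotypeTable, *omics) -> list[np.ndarray]:
    """Row orders aligning each omics matrix with the phenotype table."""
    ref = list(pheno.sample_ids)
    if len(set(ref)) != len(ref):
        raise ValueError("duplicate sample ids in phenotype table")
    orders = []
    for om in omics:
        ids = list(om.sample_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in omics matrix")
        if set(ids) != set(ref):
            raise ValueError("sample ids do not match between phenotype and omics")
        lookup = {s: i for i, s in enumerate(ids)}
        orders.append(np.array([lookup[s] for s in ref], dtype=np.intp))
    return orders


def _standardize_columns(X: np.ndarray, cols: slice | np.ndarray):
    """In-place population-convention standardization; returns centers, scales."""
    sub = X[:, cols]
    centers = sub.mean(axis=0)
    scales = sub.std(axis=0)  # population (ddof=0)
    scales = np.where(scales > 0, scales, 1.0)
    X[:, cols] = (sub - centers) / scales
    return centers, scales


def assemble_design(
    meth: MethylationMatrix | None,
    geno: GenotypeMatrix | None,
    pheno: PhenotypeTable,
    mode: str,
    pcs_meth: int = 4,
    pcs_geno: int = 4,
    standardize: bool = True,
    fraction: float = 1e-4,
    chrom_length: int | None = None,
    sqrt_group_weights: bool = True,
    eps: float = 1e-6,
) -> GroupedDesign:
    """Build the grouped design for one workflow mode.

    Modes: ``ewas`` (one size-1 group per CpG), ``gwas_general`` (one
    size-2 indicator group per SNP), ``gwas_lae`` (one size-1 numeric
    group per SNP), ``interaction`` (CpG + SNP main-effect groups plus a
    size-5 overlapped group for every colocated pair).  The covariate
    block (intercept, age, smoking, PC scores) is a single unpenalized
    group; the outcome is centered.  Penalized groups carry weight
    sqrt(d_j) unless ``sqrt_group_weights`` is off.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    need_meth = mode in ("ewas", "interaction")
    need_geno = mode in ("gwas_general", "gwas_lae", "interaction")
    if need_meth and meth is None:
        raise ValueError(f"mode {mode} requires methylation data")
    if need_geno and geno is None:
        raise ValueError(f"mode {mode} requires genotype data")

    omics = [om for om in (meth if need_meth else None, geno if need_geno else None) if om is not None]
    orders = _align_samples(pheno, *omics)
    it = iter(orders)
    if need_meth:
        meth_rows = next(it)
    if need_geno:
        geno_rows = next(it)

    n = pheno.n_samples
    y_mean = float(pheno.outcome.mean())
    y = pheno.outcome - y_mean

    # --- covariate block -------------------------------------------------
    cov_cols = [np.ones(n), pheno.age, pheno.smoking]
    cov_names = ["intercept", "age", "smoking"]
    mvals = None
    if need_meth:
        mvals = logit_mvalue(meth.values[meth_rows], eps=eps)
        if pcs_meth > 0:
            pcs = compute_pc_scores(mvals, pcs_meth)
            cov_cols.extend(pcs.T)
            cov_names.extend(f"meth_pc{i+1}" for i in range(pcs.shape[1]))
    gvals = None
    snp_general = None
    if need_geno:
        gvals = np.empty((n, geno.n_snps), dtype=float)
        raw = geno.values[geno_rows]
        for j in range(geno.n_snps):
            gj, _ = recode_minor_allele(raw[:, j])
            gvals[:, j] = impute_mode(gj)
        if pcs_geno > 0 and geno.n_snps > 0:
            pcs = compute_pc_scores(gvals, pcs_geno)
            cov_cols.extend(pcs.T)
            cov_names.extend(f"geno_pc{i+1}" for i in range(pcs.shape[1]))

    blocks: list[np.ndarray] = [np.column_stack(cov_cols)]
    groups: list[Group] = [
        Group("covariates", 0, len(cov_cols), 0.0, "covariate")
    ]
    duplication_map: dict[int, tuple] = {
        i: ("cov", name) for i, name in enumerate(cov_names)
    }
    column_meta: list[str] = ["covariate"] * 3 + ["pc_score"] * (len(cov_names) - 3)
    col = len(cov_cols)

    def w(d: int) -> float:
        return float(np.sqrt(d)) if sqrt_group_weights else 1.0

    def add_group(block: np.ndarray, gid, kind, feature, pos, sources, metas):
        nonlocal col
        d = block.shape[1]
        blocks.append(block)
        groups.append(Group(gid, col, col + d, w(d), kind, feature, int(pos)))
        for off, (src, meta_tag) in enumerate(zip(sources, metas)):
            duplication_map[col + off] = src
            column_meta.append(meta_tag)
        col += d

    if mode == "ewas":
        for j in range(meth.n_cpgs):
            add_group(
                mvals[:, [j]], str(meth.cpg_ids[j]), "cpg", (j,), meth.pos[j],
                [("cpg", j)], ["methylation"],
            )
    elif mode == "gwas_general":
        for j in range(geno.n_snps):
            ind = np.column_stack([(gvals[:, j] == 1).astype(float), (gvals[:, j] == 2).astype(float)])
            add_group(
                ind, str(geno.snp_ids[j]), "snp", (j,), geno.pos[j],
                [("snp", j, 1), ("snp", j, 2)], ["snp_indicator"] * 2,
            )
    elif mode == "gwas_lae":
        for j in range(geno.n_snps):
            add_group(
                gvals[:, [j]], str(geno.snp_ids[j]), "snp", (j,), geno.pos[j],
                [("snp", j, "lae")], ["snp_indicator"],
            )
    else:  # interaction
        snp_general = {}
        for j in range(meth.n_cpgs):
            add_group(
                mvals[:, [j]], str(meth.cpg_ids[j]), "cpg", (j,), meth.pos[j],
                [("cpg", j)], ["methylation"],
            )
        for j in range(geno.n_snps):
            ind = np.column_stack([(gvals[:, j] == 1).astype(float), (gvals[:, j] == 2).astype(float)])
            snp_general[j] = ind
            add_group(
                ind, str(geno.snp_ids[j]), "snp", (j,), geno.pos[j],
                [("snp", j, 1), ("snp", j, 2)], ["snp_indicator"] * 2,
            )
        L = int(chrom_length) if chrom_length is not None else int(
            max(meth.pos.max(initial=0), geno.pos.max(initial=0))
        )
        pairs = colocated_pairs(
            meth.pos, geno.pos, L, fraction,
            cpg_chrom=meth.chrom, snp_chrom=geno.chrom,
        )
        for jc, js in pairs:
            block = build_interaction_group(mvals[:, jc], snp_general[js])
            add_group(
                block,
                f"{meth.cpg_ids[jc]}x{geno.snp_ids[js]}",
                "interaction",
                (jc, js),
                (int(meth.pos[jc]) + int(geno.pos[js])) // 2,
                [
                    ("cpg", jc),
                    ("snp", js, 1),
                    ("snp", js, 2),
                    ("int", jc, js, 1),
                    ("int", jc, js, 2),
                ],
                ["methylation", "snp_indicator", "snp_indicator",
                 "interaction", "interaction"],
            )

    X = np.concatenate(blocks, axis=1) if len(blocks) > 1 else blocks[0]
    p = X.shape[1]
    centers = np.zeros(p)
    scales = np.ones(p)
    if standardize and p > groups[0].end:
        pen = np.arange(groups[0].end, p)
        centers[pen], scales[pen] = _standardize_columns(X, pen)
    if not np.isfinite(X).all():
        raise ValueError("design contains non-finite entries")
    return GroupedDesign(
        X=X,
        y=y,
        groups=groups,
        duplication_map=duplication_map,
        column_meta=column_meta,
        scales=scales,
        centers=centers,
        y_mean=y_mean,
        sample_ids=pheno.sample_ids.copy(),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# TSV readers (dialects documented in the writers of groupscreen.synth)

def read_feature_matrix(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].astype(str).to_numpy(dtype=object)
    feature_ids = np.array(df.columns[1:], dtype=object)
    return sample_ids, feature_ids, df.iloc[:, 1:].to_numpy()


def read_feature_meta(path):
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for c in ("feature_id", "chrom", "pos"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return df


def read_phenotype(path) -> PhenotypeTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for c in ("sample_id", "outcome", "age", "smoking"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return PhenotypeTable(
        sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
        outcome=df["outcome"].to_numpy(dtype=float),
        age=df["age"].to_numpy(dtype=float),
        smoking=df["smoking"].to_numpy(dtype=float),
    )


def _ordered_meta(meta, feature_ids, path):
    meta = meta.set_index("feature_id")
    missing = [f for f in feature_ids if f not in meta.index]
    if missing:
        raise ValueError(f"{path}: metadata missing for features {missing[:5]}...")
    sub = meta.loc[list(feature_ids)]
    return sub["chrom"].to_numpy(dtype=object), sub["pos"].to_numpy(dtype=np.int64)


def load_methylation(matrix_path, meta_path) -> MethylationMatrix:
    sample_ids, feature_ids, values = read_feature_matrix(matrix_path)
    chrom, pos = _ordered_meta(read_feature_meta(meta_path), feature_ids, meta_path)
    return MethylationMatrix(
        values=values, cpg_ids=feature_ids, chrom=chrom, pos=pos, sample_ids=sample_ids
    )


def load_genotypes(matrix_path, meta_path) -> GenotypeMatrix:
    sample_ids, feature_ids, values = read_feature_matrix(matrix_path)
    chrom, pos = _ordered_meta(read_feature_meta(meta_path), feature_ids, meta_path)
    values = values.astype(np.int64)
    freq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        obs = values[:, j][values[:, j] != MISSING_GENOTYPE]
        freq[j] = obs.mean() / 2.0 if obs.size else 0.0
    maf = np.clip(np.minimum(freq, 1.0 - freq), 1e-9, 0.5)
    return GenotypeMatrix(
        values=values, snp_ids=feature_ids, chrom=chrom, pos=pos, maf=maf,
        sample_ids=sample_ids,
    )
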