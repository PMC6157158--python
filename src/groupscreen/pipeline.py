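"""End-to-end screening workflows: EWAS, GWAS, and the interaction model.

Each workflow assembles its grouped design, picks the penalty by
cross-validation on the full data, runs complementary-pairs stability
selection at that penalty, calibrates the frequency threshold tau for
the target per-family error rate, and produces report tables: a
Manhattan export of -log(1 - pi_hat) (natural log) by genomic position
and a ranked top table.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, MethylationMatrix, PhenotypeTable
from .design import GroupedDesign, assemble_design
from .solver import PenaltyConfig, cv_select_lambda, fit
from .stability import (
    ErrorBound,
    StabilityResult,
    make_plan,
    pfer_bound,
    run,
    select,
    tau_for_pfer,
)

__all__ = [
    "PipelineConfig",
    "WorkflowResult",
    "run_ewas",
    "run_gwas",
    "run_interaction",
    "manhattan_export",
    "top_table",
]


@dataclass
class PipelineConfig:
    """Tunable settings shared by the three workflows."""

    B: int = 50  # complementary pairs (2B half-sample fits)
    w_low: float = 0.5  # lower end of the penalty-randomization factor
    target_ev: float = 0.05  # per-family error rate target E[V]
    tau: float | None = None  # fixed threshold; None = calibrate from target_ev
    fraction: float = 1e-4  # colocation window as fraction of chromosome length
    chrom_length: int | None = None
    pcs_meth: int = 4
    pcs_geno: int = 4
    folds: int = 5
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    lambda2_ratio: float = 1e-3
    coding: str = "general"  # GWAS genotype coding: general | lae
    standardize: bool = True
    sqrt_group_weights: bool = True
    max_sweeps: int = 2000
    # Subsample and CV fits feed support detection only; their accuracy
    # requirement is far looser than a single final fit's, and half-sample
    # designs with n < p and a slight ridge converge slowly below this.
    tol: float = 1e-6
    strict: bool = True
    seed: int = 0


@dataclass
class WorkflowResult:
    mode: str
    design: GroupedDesign
    stability: StabilityResult
    selected: set
    tau: float
    bound: ErrorBound | None
    lambda1: float
    cv_errors: np.ndarray
    lambda_grid: np.ndarray
    record: dict = field(default_factory=dict)

    @property
    def manhattan(self) -> pd.DataFrame:
        return manhattan_export(self.stability, self.design.groups)

    def top(self, k: int = 10) -> pd.DataFrame:
        return top_table(self.stability, self.design.groups, k, self.tau)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _run_workflow(design: GroupedDesign, config: PipelineConfig, mode: str) -> WorkflowResult:
    cv_seed, plan_seed, stab_seed = _sub_seeds(config.seed, 3)
    base = PenaltyConfig(
        lambda2_ratio=config.lambda2_ratio,
        max_sweeps=config.max_sweeps,
        tol=config.tol,
    )
    lam1, cv_errors, grid = cv_select_lambda(
        design,
        folds=config.folds,
        penalty_base=base,
        seed=cv_seed,
        n_lambda=config.n_lambda,
        min_ratio=config.lambda_min_ratio,
    )
    penalty = base.with_lambda1(lam1)
    warm = fit(design, penalty, check_kkt=False).beta
    plan = make_plan(design.n_samples, config.B, seed=plan_seed)
    stab = run(
        design,
        penalty,
        plan,
        w_low=config.w_low,
        seed=stab_seed,
        strict=config.strict,
        warm_start=warm,
    )
    p_groups = len(design.penalized_groups)
    if config.tau is not None:
        tau = float(config.tau)
        bound = (
            pfer_bound(tau, stab.q_hat, p_groups, config.B)
            if stab.q_hat > 0
            else None
        )
    elif stab.q_hat <= 0:
        tau, bound = 1.0, None  # nothing was ever selected
    else:
        try:
            bound = tau_for_pfer(config.target_ev, stab.q_hat, p_groups, config.B)
            tau = bound.tau
        except ValueError:
            # Even tau = 1 cannot certify the target: select nothing.
            tau, bound = 1.0, pfer_bound(1.0, stab.q_hat, p_groups, config.B)
    selected = select(stab, tau)
    record = {
        "mode": mode,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": asdict(config),
        "seeds": {"cv": cv_seed, "plan": plan_seed, "stability": stab_seed},
        "n_samples": int(design.n_samples),
        "n_penalized_groups": int(p_groups),
        "lambda1": float(lam1),
        "lambda2": float(penalty.resolved_lambda2),
        "q_hat": float(stab.q_hat),
        "tau": float(tau),
        "ev_bound": None if bound is None else float(bound.ev_bound),
        "bound_method": None if bound is None else bound.method,
        "n_selected": int(len(selected)),
    }
    return WorkflowResult(
        mode=mode,
        design=design,
        stability=stab,
        selected=selected,
        tau=tau,
        bound=bound,
        lambda1=lam1,
        cv_errors=cv_errors,
        lambda_grid=grid,
        record=record,
    )


def run_ewas(
    meth: MethylationMatrix, pheno: PhenotypeTable, config: PipelineConfig | None = None
) -> WorkflowResult:
    """Epigenome-wide screen: outcome on logit methylation, adjusted for
    age, smoking and the leading methylation principal components."""
    config = config or PipelineConfig()
    design = assemble_design(
        meth, None, pheno, "ewas",
        pcs_meth=config.pcs_meth, pcs_geno=0,
        standardize=config.standardize,
        sqrt_group_weights=config.sqrt_group_weights,
    )
    return _run_workflow(design, config, "ewas")


def run_gwas(
    geno: GenotypeMatrix, pheno: PhenotypeTable, config: PipelineConfig | None = None
) -> WorkflowResult:
    """Genome-wide screen with categorical (``general``) or allele-count
    (``lae``) genotype coding, adjusted for age, smoking and genotype PCs."""
    config = config or PipelineConfig()
    if config.coding not in ("general", "lae"):
        raise ValueError(f"coding must be 'general' or 'lae', got {config.coding!r}")
    mode = "gwas_general" if config.coding == "general" else "gwas_lae"
    design = assemble_design(
        None, geno, pheno, mode,
        pcs_meth=0, pcs_geno=config.pcs_geno,
        standardize=config.standardize,
        sqrt_group_weights=config.sqrt_group_weights,
    )
    return _run_workflow(design, config, mode)


def run_interaction(
    meth: MethylationMatrix,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    config: PipelineConfig | None = None,
) -> WorkflowResult:
    """Single-chromosome CpG-by-SNP interaction screen.

    Builds main-effect groups for every CpG and SNP plus a size-5
    strong-hierarchy group for every colocated pair, adjusting for age,
    smoking, and both methylation and genotype principal components.
    """
    config = config or PipelineConfig()
    chroms = set(meth.chrom.tolist()) | set(geno.chrom.tolist())
    if len(chroms) != 1:
        raise ValueError(
            f"interaction screen requires a single chromosome, got {sorted(chroms)}"
        )
    design = assemble_design(
        meth, geno, pheno, "interaction",
        pcs_meth=config.pcs_meth, pcs_geno=config.pcs_geno,
        standardize=config.standardize,
        sqrt_group_weights=config.sqrt_group_weights,
        fraction=config.fraction,
        chrom_length=config.chrom_length,
    )
    return _run_workflow(design, config, "interaction")


def manhattan_export(result: StabilityResult, groups, chrom=None) -> pd.DataFrame:
    """Table of (chrom, position, -log(1 - pi_hat), kind) per penalized group.

    Natural logarithm; pi_hat = 1 is capped at -log(1/(4B)) to stay
    finite.  Interaction groups sit at the floor midpoint of their CpG
    and SNP positions (set when the design was assembled); rows are
    sorted by position.
    """
    rows = []
    floor_frac = 1.0 / (4.0 * result.B)
    for j, g in enumerate(groups):
        if not g.penalized:
            continue
        pi = float(result.pi_hat[j])
        miss = 1.0 - pi
        value = -np.log(max(miss, floor_frac)) if pi > 0 else 0.0
        rows.append(
            {
                "group_id": g.gid,
                "kind": g.kind,
                "pos": int(g.pos),
                "pi_hat": pi,
                "neglog_not_selected": value,
            }
        )
        if g.pos <= 0:
            raise ValueError(f"group {g.gid} has no mapped position")
    df = pd.DataFrame(rows).sort_values("pos", kind="stable").reset_index(drop=True)
    return df


def top_table(result: StabilityResult, groups, k: int = 10, tau: float = 0.0) -> pd.DataFrame:
    """Top-k groups by selection frequency (ties: smaller position first).

    Interaction rows are flagged with whether their constituent CpG
    and/or SNP main-effect group is itself above the threshold tau.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    main_pi = {}
    for j, g in enumerate(groups):
        if g.kind in ("cpg", "snp"):
            main_pi[(g.kind, g.feature[0])] = float(result.pi_hat[j])
    rows = []
    for j, g in enumerate(groups):
        if not g.penalized:
            continue
        pi = float(result.pi_hat[j])
        flag = ""
        if g.kind == "interaction":
            jc, js = g.feature
            parts = []
            if main_pi.get(("cpg", jc), 0.0) > tau:
                parts.append("CpG")
            if main_pi.get(("snp", js), 0.0) > tau:
                parts.append("SNP")
            flag = "+".join(parts) if parts else "No"
        rows.append(
            {
                "group_id": g.gid,
                "kind": g.kind,
                "pos": int(g.pos),
                "pi_hat": pi,
                "marginally_significant": flag,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["pi_hat", "pos"], ascending=[False, True], kind="stable"
    )
    return df.head(k).reset_index(drop=True)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
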