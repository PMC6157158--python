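"""Complementary-pairs stability selection around a group-selection fit.

Each of B draws splits the samples into two disjoint halves of size
floor(n/2) (for odd n one sample per draw is left out); the selection
procedure runs on all 2B halves with the group penalty randomly
rescaled per half, and a group's selection frequency pi_hat is the
fraction of halves that selected it.  The expected number of false
selections above a frequency threshold tau is bounded by
E[V] <= p * M(tau, q, p) (see :mod:`groupscreen._bounds`), where q is
the average number of groups selected per half-sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._bounds import ErrorBound, pfer_bound, rconcave_tail, tau_for_pfer
from .design import GroupedDesign
from .solver import FitResult, PenaltyConfig, fit

__all__ = [
    "SubsamplePlan",
    "StabilityResult",
    "ErrorBound",
    "make_plan",
    "randomize_weights",
    "run",
    "select",
    "pfer_bound",
    "tau_for_pfer",
    "rconcave_tail",
]


@dataclass(frozen=True)
class SubsamplePlan:
    """B complementary pairs of disjoint half-sample index sets."""

    pairs: tuple  # of (half_a, half_b) index-array pairs
    n: int
    seed: int

    @property
    def B(self) -> int:
        return len(self.pairs)

    def halves(self):
        """The 2B half-samples in order (pair 0 first half, second half, ...)."""
        for a, b in self.pairs:
            yield a
            yield b


def make_plan(n: int, B: int, seed: int = 0) -> SubsamplePlan:
    """Seeded uniform shuffle-splits into complementary halves of floor(n/2)."""
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    if B < 1:
        raise ValueError(f"need B >= 1 pairs, got {B}")
    rng = np.random.default_rng(seed)
    h = n // 2
    pairs = []
    for _ in range(B):
        perm = rng.permutation(n)
        pairs.append((np.sort(perm[:h]), np.sort(perm[h : 2 * h])))
    return SubsamplePlan(pairs=tuple(pairs), n=n, seed=seed)


def randomize_weights(
    groups, w_low: float = 0.5, seed: int = 0, per_column: bool = False
) -> np.ndarray:
    """Multiplicative penalty factors, uniform on [w_low, 1] per group.

    Unpenalized groups keep factor 1.  Selection is group-wise, so the
    rescaling is per group by default; ``per_column`` draws one factor
    per design column and averages within each group.
    """
    if not (0.0 < w_low <= 1.0):
        raise ValueError(f"w_low must be in (0, 1], got {w_low}")
    rng = np.random.default_rng(seed)
    factors = np.ones(len(groups))
    for j, g in enumerate(groups):
        if not g.penalized:
            continue
        if per_column:
            factors[j] = float(rng.uniform(w_low, 1.0, size=g.size).mean())
        else:
            factors[j] = float(rng.uniform(w_low, 1.0))
    return factors


@dataclass
class StabilityResult:
    """Selection frequencies over the 2B half-sample fits."""

    pi_hat: np.ndarray  # per group (0 for unpenalized groups)
    B: int
    q_hat: float  # average number of penalized groups selected per half
    per_half_selected: tuple  # frozenset of group indices per half
    seed: int
    group_ids: tuple = ()
    penalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = self.pi_hat * (2 * self.B)
        if not np.allclose(counts, np.round(counts), atol=1e-9):
            raise ValueError("pi_hat values must be multiples of 1/(2B)")


def _default_fit_fn(sub: GroupedDesign, penalty: PenaltyConfig, beta0):
    res: FitResult = fit(sub, penalty, beta0=beta0, check_kkt=False)
    return res.active_groups, res.converged


def run(
    design: GroupedDesign,
    penalty: PenaltyConfig,
    plan: SubsamplePlan,
    w_low: float = 0.5,
    seed: int = 0,
    fit_fn=None,
    strict: bool = True,
    warm_start: np.ndarray | None = None,
) -> StabilityResult:
    """Stability selection at a fixed penalty over a subsample plan.

    ``penalty`` is meant to be fixed in advance (typically the full-data
    cross-validated choice).  Each half-sample fit sees its own seeded
    weight randomization.  ``fit_fn(sub_design, penalty, beta0) ->
    (selected_group_indices, converged)`` may replace the solver (test
    harness / alternative selectors).  By default a non-converged half
    raises; with ``strict=False`` it is recorded and excluded from the
    frequencies.
    """
    if plan.n != design.n_samples:
        raise ValueError("plan was built for a different sample count")
    if fit_fn is None:
        fit_fn = _default_fit_fn
    ng = len(design.groups)
    pen_mask = np.array([g.penalized for g in design.groups])
    counts = np.zeros(ng)
    selected_sets = []
    total_selected = 0
    n_halves = 0
    failed = []
    ss = np.random.SeedSequence(seed)
    half_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2 * plan.B)]
    for h, rows in enumerate(plan.halves()):
        factors = randomize_weights(design.groups, w_low=w_low, seed=half_seeds[h])
        pen_h = PenaltyConfig(
            lambda1=penalty.lambda1,
            lambda2=penalty.lambda2,
            lambda2_ratio=penalty.lambda2_ratio,
            group_weights=factors,
            max_sweeps=penalty.max_sweeps,
            tol=penalty.tol,
            kkt_tol=penalty.kkt_tol,
        )
        sub = design.subset_rows(rows)
        selected, converged = fit_fn(sub, pen_h, warm_start)
        if not converged:
            if strict:
                raise RuntimeError(f"half-sample fit {h} did not converge")
            failed.append(h)
            selected_sets.append(frozenset())
            continue
        selected = frozenset(int(j) for j in selected if pen_mask[j])
        selected_sets.append(selected)
        for j in selected:
            counts[j] += 1
        total_selected += len(selected)
        n_halves += 1
    if n_halves == 0:
        raise RuntimeError("no half-sample fit converged")
    pi_hat = counts / (2 * plan.B)  # excluded halves count as not-selected
    q_hat = total_selected / n_halves
    return StabilityResult(
        pi_hat=pi_hat,
        B=plan.B,
        q_hat=float(q_hat),
        per_half_selected=tuple(selected_sets),
        seed=seed,
        group_ids=tuple(g.gid for g in design.groups),
        penalized=pen_mask,
    )


def select(result: StabilityResult, tau: float) -> set:
    """Groups whose selection frequency strictly exceeds ``tau``."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    pen = result.penalized
    return {
        int(j)
        for j in np.nonzero(result.pi_hat > tau)[0]
        if pen is None or pen[j]
    }


def write_stability_tsv(result: StabilityResult, path) -> None:
    """Group id and selection frequency, one row per penalized group."""
    import pandas as pd

    pen = (
        result.penalized
        if result.penalized is not None
        else np.ones(len(result.pi_hat), dtype=bool)
    )
    idx = np.nonzero(pen)[0]
    pd.DataFrame(
        {
            "group_id": [result.group_ids[j] if result.group_ids else str(j) for j in idx],
            "pi_hat": result.pi_hat[idx],
        }
    ).to_csv(path, sep="\t", index=False)
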