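"""Elastic-net group LASSO by block-coordinate descent.

Minimizes, over coefficient vector beta partitioned into groups j,

    (1/2n) ||y - X beta||^2  +  lambda1 * sum_j w_j ||beta_j||_2
                             +  (lambda2/2) * ||beta_pen||^2

where w_j >= 0 are group penalty weights (w_j = 0 marks the unpenalized
covariate block, solved exactly by least squares within each sweep) and
the ridge term runs over penalized columns only.  Each penalized block
is updated by a majorize-minimize proximal step with per-group
Lipschitz constant L_j = lambda_max(X_j^T X_j)/n + lambda2, which makes
the objective non-increasing at every sweep and produces exact zeros.

The sweep kernel is JIT-compiled; sweeps cycle in fixed ascending group
order, alternating full sweeps with sweeps restricted to the currently
active groups (convergence is only declared after a full sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba as nb
import numpy as np

from .design import GroupedDesign

__all__ = [
    "PenaltyConfig",
    "FitResult",
    "group_soft_threshold",
    "fit",
    "kkt_violation",
    "lambda_max",
    "lambda_grid",
    "cv_select_lambda",
    "recover_effects",
]

DEFAULT_LAMBDA2_RATIO = 1e-3  # "slight" ridge relative to lambda1


@dataclass
class PenaltyConfig:
    """Penalty and convergence settings for one fit.

    ``lambda2=None`` resolves to ``lambda2_ratio * lambda1``.
    ``group_weights`` are multiplicative per-group factors on top of the
    design's own w_j (used for stability-selection randomization).
    """

    lambda1: float = 0.0
    lambda2: float | None = None
    lambda2_ratio: float = DEFAULT_LAMBDA2_RATIO
    group_weights: np.ndarray | None = None
    max_sweeps: int = 2000
    tol: float = 1e-8
    kkt_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.lambda2 is not None and self.lambda2 < 0:
            raise ValueError("lambda2 must be >= 0")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")

    @property
    def resolved_lambda2(self) -> float:
        if self.lambda2 is not None:
            return float(self.lambda2)
        return self.lambda2_ratio * self.lambda1

    def with_lambda1(self, lam1: float) -> "PenaltyConfig":
        return PenaltyConfig(
            lambda1=lam1,
            lambda2=self.lambda2,
            lambda2_ratio=self.lambda2_ratio,
            group_weights=self.group_weights,
            max_sweeps=self.max_sweeps,
            tol=self.tol,
            kkt_tol=self.kkt_tol,
        )


@dataclass
class FitResult:
    beta: np.ndarray
    intercept: float
    active_groups: set
    objective: float
    sweeps_used: int
    converged: bool
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    kkt: float = float("nan")


def group_soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of t*||.||_2: shrink the block toward zero.

    Returns 0 when ||z|| <= t, else (1 - t/||z||) z.
    """
    z = np.asarray(z, dtype=float)
    if t < 0:
        raise ValueError("threshold must be >= 0")
    nrm = float(np.linalg.norm(z))
    if nrm <= t:
        return np.zeros_like(z)
    return (1.0 - t / nrm) * z


# ---------------------------------------------------------------------------
# compiled kernels
#
# The two hot loops (column-residual dot products and residual updates)
# are isolated with fastmath=True so the reductions vectorize; order of
# operations is fixed at compile time, so results stay deterministic.


@nb.njit(cache=True, fastmath=True, inline="always")
def _dot_col(X, col, r):
    acc = 0.0
    for i in range(r.shape[0]):
        acc += X[i, col] * r[i]
    return acc


@nb.njit(cache=True, fastmath=True, inline="always")
def _axpy_col(X, col, r, delta):
    for i in range(r.shape[0]):
        r[i] -= X[i, col] * delta


@nb.njit(cache=True)
def _group_lipschitz(X, gstart, gend, weight):
    """Largest eigenvalue of X_j^T X_j / n per penalized group (0 otherwise)."""
    ng = gstart.shape[0]
    n = X.shape[0]
    L = np.zeros(ng)
    maxd = 0
    for j in range(ng):
        if gend[j] - gstart[j] > maxd:
            maxd = gend[j] - gstart[j]
    gram = np.empty((maxd, maxd))
    v = np.empty(maxd)
    w = np.empty(maxd)
    for j in range(ng):
        if weight[j] == 0.0:
            continue
        s, e = gstart[j], gend[j]
        d = e - s
        if d == 1:
            lmax = _dot_col(X, s, X[:, s]) / n
        else:
            for a in range(d):
                for b in range(a, d):
                    gram[a, b] = _dot_col(X, s + a, X[:, s + b]) / n
                    gram[b, a] = gram[a, b]
            # power iteration on the (tiny) Gram matrix
            inv_sqrt_d = 1.0 / np.sqrt(d)
            for a in range(d):
                v[a] = inv_sqrt_d
            lmax = 0.0
            for _ in range(128):
                nrm = 0.0
                for a in range(d):
                    acc = 0.0
                    for b in range(d):
                        acc += gram[a, b] * v[b]
                    w[a] = acc
                    nrm += acc * acc
                nrm = np.sqrt(nrm)
                if nrm <= 1e-300:
                    lmax = 0.0
                    break
                new = 0.0
                for a in range(d):
                    v[a] = w[a] / nrm
                for a in range(d):
                    acc = 0.0
                    for b in range(d):
                        acc += gram[a, b] * v[b]
                    new += v[a] * acc
                if abs(new - lmax) <= 1e-13 * max(new, 1.0):
                    lmax = new
                    break
                lmax = new
        L[j] = max(lmax, 1e-12)
    return L


@nb.njit(cache=True)
def _one_sweep(X, r, beta, gstart, gend, weight, L, lam1, lam2, active,
               only_active, cov_j, cov_inv, zbuf):
    n = X.shape[0]
    ng = gstart.shape[0]
    for j in range(ng):
        s, e = gstart[j], gend[j]
        d = e - s
        if weight[j] == 0.0:
            if only_active:
                continue
            # exact least squares on the partial residual
            for a in range(d):
                zbuf[a] = _dot_col(X, s + a, r)
            for a in range(d):
                delta = 0.0
                for b in range(d):
                    delta += cov_inv[a, b] * zbuf[b]
                if delta != 0.0:
                    beta[s + a] += delta
                    _axpy_col(X, s + a, r, delta)
            continue
        if only_active and not active[j]:
            continue
        Lj = L[j]
        thr = lam1 * weight[j] / Lj
        zz = 0.0
        shrink = 1.0 - lam2 / Lj
        for a in range(d):
            col = s + a
            z = beta[col] * shrink + _dot_col(X, col, r) / (n * Lj)
            zbuf[a] = z
            zz += z * z
        znorm = np.sqrt(zz)
        scale = 0.0 if znorm <= thr else 1.0 - thr / znorm
        isactive = False
        for a in range(d):
            col = s + a
            newv = scale * zbuf[a]
            delta = newv - beta[col]
            if delta != 0.0:
                beta[col] = newv
                _axpy_col(X, col, r, delta)
            if newv != 0.0:
                isactive = True
        active[j] = isactive


@nb.njit(cache=True)
def _objective(r, beta, gstart, gend, weight, lam1, lam2, n):
    rss = 0.0
    for i in range(r.shape[0]):
        rss += r[i] * r[i]
    obj = 0.5 * rss / n
    ng = gstart.shape[0]
    for j in range(ng):
        if weight[j] == 0.0:
            continue
        acc = 0.0
        for c in range(gstart[j], gend[j]):
            acc += beta[c] * beta[c]
        obj += lam1 * weight[j] * np.sqrt(acc) + 0.5 * lam2 * acc
    return obj


@nb.njit(cache=True)
def _solve(X, r, beta, gstart, gend, weight, L, lam1, lam2, tol, max_sweeps,
           cov_j, cov_inv, obj_hist):
    n = X.shape[0]
    ng = gstart.shape[0]
    maxd = 0
    for j in range(ng):
        d = gend[j] - gstart[j]
        if d > maxd:
            maxd = d
    zbuf = np.empty(maxd)
    active = np.zeros(ng, nb.boolean)
    for j in range(ng):
        for c in range(gstart[j], gend[j]):
            if beta[c] != 0.0:
                active[j] = True
                break
    sweeps = 0
    converged = False
    prev = np.inf
    obj = np.inf
    while sweeps < max_sweeps:
        _one_sweep(X, r, beta, gstart, gend, weight, L, lam1, lam2, active,
                   False, cov_j, cov_inv, zbuf)
        obj = _objective(r, beta, gstart, gend, weight, lam1, lam2, n)
        obj_hist[sweeps] = obj
        sweeps += 1
        if prev - obj <= tol * max(abs(prev), 1.0) and np.isfinite(prev):
            converged = True
            break
        prev = obj
        while sweeps < max_sweeps:
            _one_sweep(X, r, beta, gstart, gend, weight, L, lam1, lam2, active,
                       True, cov_j, cov_inv, zbuf)
            obj = _objective(r, beta, gstart, gend, weight, lam1, lam2, n)
            obj_hist[sweeps] = obj
            sweeps += 1
            if prev - obj <= tol * max(abs(prev), 1.0):
                prev = obj
                break
            prev = obj
    return sweeps, converged, obj


# ---------------------------------------------------------------------------


def _group_arrays(design: GroupedDesign, factors: np.ndarray | None):
    ng = len(design.groups)
    gstart = np.array([g.start for g in design.groups], dtype=np.int64)
    gend = np.array([g.end for g in design.groups], dtype=np.int64)
    weight = np.array([g.weight for g in design.groups], dtype=float)
    if factors is not None:
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (ng,):
            raise ValueError("group_weights must have one factor per group")
        weight = weight * factors
    unpen = [j for j, g in enumerate(design.groups) if not g.penalized]
    if len(unpen) > 1:
        raise ValueError("at most one unpenalized group is supported")
    cov_j = unpen[0] if unpen else -1
    if cov_j >= 0:
        Xc = design.X[:, gstart[cov_j] : gend[cov_j]]
        gram = Xc.T @ Xc
        cov_inv = np.linalg.pinv(gram)
    else:
        cov_inv = np.zeros((1, 1))
    return gstart, gend, weight, cov_j, cov_inv


def fit(
    design: GroupedDesign,
    penalty: PenaltyConfig,
    beta0: np.ndarray | None = None,
    check_kkt: bool = True,
) -> FitResult:
    """Solve the penalized problem on ``design``; warm-startable via ``beta0``."""
    X = design.X
    if not np.isfinite(X).all() or not np.isfinite(design.y).all():
        raise ValueError("design contains non-finite entries")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    lam1 = float(penalty.lambda1)
    lam2 = penalty.resolved_lambda2
    gstart, gend, weight, cov_j, cov_inv = _group_arrays(design, penalty.group_weights)
    # Fortran layout and per-group curvature depend only on the design;
    # cache them so warm-started path and stability fits reuse both.
    Xf = getattr(design, "_solver_Xf", None)
    if Xf is None or Xf.shape != X.shape:
        Xf = np.asfortranarray(X)
        design._solver_Xf = Xf
    lmax = getattr(design, "_solver_lmax", None)
    if lmax is None:
        lmax = _group_lipschitz(Xf, gstart, gend, weight)
        design._solver_lmax = lmax
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float, copy=True)
    r = design.y - Xf @ beta if beta0 is not None else design.y.copy()
    L = np.where(lmax > 0, lmax + lam2, 0.0)
    obj_hist = np.empty(penalty.max_sweeps)
    tol = penalty.tol
    sweeps_total = 0
    converged = False
    for round_ in range(3):
        budget = penalty.max_sweeps - sweeps_total
        if budget <= 0:
            break
        sweeps, converged, obj = _solve(
            Xf, r, beta, gstart, gend, weight, L, lam1, lam2, tol,
            budget, cov_j, cov_inv, obj_hist[sweeps_total:],
        )
        sweeps_total += sweeps
        if not check_kkt:
            break
        kkt = _kkt(Xf, r, beta, gstart, gend, weight, lam1, lam2)
        if kkt <= penalty.kkt_tol or not converged:
            break
        tol *= 1e-3  # objective plateaued before stationarity: tighten
    nz_cols = np.flatnonzero(beta)
    nz_groups = np.unique(np.searchsorted(gstart, nz_cols, side="right") - 1)
    active = {int(j) for j in nz_groups if weight[j] > 0.0}
    obj = _objective(r, beta, gstart, gend, weight, lam1, lam2, n)
    kkt = (
        _kkt(Xf, r, beta, gstart, gend, weight, lam1, lam2)
        if check_kkt
        else float("nan")
    )
    intercept = design.y_mean
    if cov_j >= 0:
        intercept += beta[gstart[cov_j]]  # intercept column is first covariate
    return FitResult(
        beta=beta,
        intercept=float(intercept),
        active_groups=active,
        objective=float(obj),
        sweeps_used=sweeps_total,
        converged=bool(converged),
        objective_history=obj_hist[:sweeps_total].copy(),
        kkt=float(kkt),
    )


def _kkt(X, r, beta, gstart, gend, weight, lam1, lam2) -> float:
    n = X.shape[0]
    G = X.T @ r / n
    worst = 0.0
    for j in range(gstart.shape[0]):
        if weight[j] == 0.0:
            v = float(np.max(np.abs(G[gstart[j] : gend[j]]), initial=0.0))
            worst = max(worst, v)
            continue
        b = beta[gstart[j] : gend[j]]
        g = G[gstart[j] : gend[j]]
        nrm = float(np.linalg.norm(b))
        if nrm > 0:
            v = float(np.max(np.abs(g - lam2 * b - lam1 * weight[j] * b / nrm)))
        else:
            v = max(0.0, float(np.linalg.norm(g)) - lam1 * weight[j])
        worst = max(worst, v)
    return worst


def kkt_violation(design: GroupedDesign, penalty: PenaltyConfig, result: FitResult) -> float:
    """Max stationarity violation of ``result`` on this design/penalty.

    Active groups check the gradient equation; inactive groups check the
    subgradient ball ||X_j^T r / n|| <= lambda1 w_j.
    """
    gstart, gend, weight, _, _ = _group_arrays(design, penalty.group_weights)
    r = design.y - design.X @ result.beta
    return _kkt(
        design.X, r, result.beta, gstart, gend, weight,
        penalty.lambda1, penalty.resolved_lambda2,
    )


def lambda_max(design: GroupedDesign, penalty: PenaltyConfig | None = None) -> float:
    """Smallest lambda1 that zeroes every penalized block (KKT at 0).

    Uses the residual of the covariate-only least-squares fit:
    max_j ||X_j^T r||_2 / (n w_j).
    """
    gstart, gend, weight, cov_j, cov_inv = _group_arrays(
        design, None if penalty is None else penalty.group_weights
    )
    y = design.y
    if cov_j >= 0:
        Xc = design.X[:, gstart[cov_j] : gend[cov_j]]
        r = y - Xc @ (cov_inv @ (Xc.T @ y))
    else:
        r = y
    n = design.n_samples
    G = design.X.T @ r / n
    lam = 0.0
    for j in range(len(design.groups)):
        if weight[j] == 0.0:
            continue
        lam = max(lam, float(np.linalg.norm(G[gstart[j] : gend[j]])) / weight[j])
    return lam


def lambda_grid(
    design: GroupedDesign,
    penalty: PenaltyConfig | None = None,
    n_lambda: int = 50,
    min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(design, penalty)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def fit_path(
    design: GroupedDesign,
    grid: np.ndarray,
    penalty_base: PenaltyConfig,
    check_kkt: bool = False,
):
    """Warm-started fits along a descending lambda1 grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValueError("lambda grid must be descending")
    results = []
    beta = None
    for lam in grid:
        res = fit(design, penalty_base.with_lambda1(float(lam)), beta0=beta,
                  check_kkt=check_kkt)
        beta = res.beta
        results.append(res)
    return results


def cv_select_lambda(
    design: GroupedDesign,
    lambda_grid_values: np.ndarray | None = None,
    folds: int = 5,
    penalty_base: PenaltyConfig | None = None,
    seed: int = 0,
    n_lambda: int = 50,
    min_ratio: float = 1e-3,
):
    """K-fold cross-validation of mean squared prediction error.

    Folds are a seeded partition of the samples; fits along the
    descending grid are warm-started.  Returns ``(best_lambda,
    cv_errors, grid)`` with ties resolved toward the larger lambda.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if penalty_base is None:
        penalty_base = PenaltyConfig()
    if lambda_grid_values is None:
        grid = lambda_grid(design, penalty_base, n_lambda=n_lambda, min_ratio=min_ratio)
    else:
        grid = np.asarray(lambda_grid_values, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if (grid <= 0).any():
        raise ValueError("lambda grid must contain positive values only")
    n = design.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, folds)):
        fold_ids[chunk] = k
    errs = np.zeros((folds, grid.size))
    for k in range(folds):
        val = fold_ids == k
        train = ~val
        sub = design.subset_rows(np.where(train)[0])
        path = fit_path(sub, grid, penalty_base)
        Xv, yv = design.X[val], design.y[val]
        for i, res in enumerate(path):
            pred = Xv @ res.beta
            errs[k, i] = float(np.mean((yv - pred) ** 2))
    mean_err = errs.mean(axis=0)
    best = int(np.argmin(mean_err))  # grid descends: first minimizer = largest lambda
    return float(grid[best]), mean_err, grid


def recover_effects(result: FitResult, design: GroupedDesign) -> dict:
    """Total coefficient per source feature, on the original column scale.

    Sums, over all design columns representing a source feature (main
    copies and interaction copies alike), the fitted coefficient divided
    by the standardization scale of that column.
    """
    out: dict = {}
    scales = design.scales
    for col in range(design.n_columns):
        if col not in design.duplication_map:
            raise KeyError(f"design column {col} missing from duplication_map")
        key = design.duplication_map[col]
        out[key] = out.get(key, 0.0) + float(result.beta[col]) / float(scales[col])
    return out
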