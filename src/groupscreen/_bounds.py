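"""Per-family-error-rate bounds for complementary-pairs stability selection.

Implements the expected-false-selection bound E[V] <= p * M(tau, q, p)
for complementary-pairs subsampling: the basic bound valid for
thresholds above one half, together with the sharper r-concave tail
bounds of the Shah--Samworth theory.  The r-concave bounds treat the
empirical selection frequency of a null group as a random variable on
the grid {0, 1/B, ..., 1} whose distribution is assumed r-concave; the
worst-case tail probability over that class, subject to the mean
constraint implied by the average number of selections q, is computed
by an exact extremal-distribution search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["ErrorBound", "rconcave_tail", "pfer_bound", "tau_for_pfer"]


@dataclass(frozen=True)
class ErrorBound:
    """A selection threshold paired with its bound on E[V].

    Attributes
    ----------
    tau : selection-frequency threshold in (0, 1].
    p : number of penalized (selectable) groups.
    q : average number of groups selected per half-sample.
    B : number of complementary pairs (2B half-sample fits).
    ev_bound : bound on the expected number of falsely selected groups.
    method : which branch of the bound family attained the minimum.
    """

    tau: float
    p: int
    q: float
    B: int
    ev_bound: float
    method: str
    trivial_regime: bool = False
    branches: dict | None = None
    """Per-branch values of p*M, keyed by branch name (diagnostics)."""


def _extremal_tail(theta: float, i_min: int, B: int, s: float, k: int) -> float:
    """Worst-case tail P(X >= i_min/B) over pmfs f on {0..k} with f^(1/s)
    linear (the extremal r-concave shape, s = 1/r < 0) and mean theta*B."""
    i = np.arange(k + 1, dtype=float)
    mean_target = theta * B

    def mean_of(c: float) -> float:
        w = np.power(1.0 + c * i, s)
        return float(np.dot(i, w) / w.sum())

    # mean_of is strictly decreasing in c; support truncated below B
    # requires c >= 0 or the r-scale sequence would lose convexity at k.
    c_lo = 0.0 if k < B else -1.0 / B + 1e-12
    if mean_of(c_lo) < mean_target:
        return 0.0  # mean unreachable on this support
    c_hi = 1.0
    while mean_of(c_hi) > mean_target:
        c_hi *= 4.0
        if c_hi > 1e12:  # pragma: no cover - mass collapses to zero
            return 0.0
    c = brentq(lambda t: mean_of(t) - mean_target, c_lo, c_hi, xtol=1e-14, rtol=1e-14)
    w = np.power(1.0 + c * i, s)
    return float(w[i_min:].sum() / w.sum())


def rconcave_tail(theta: float, x: float, B: int, r: float) -> float:
    """Maximal P(X >= x) over r-concave pmfs on {0, 1/B, ..., 1} with mean theta.

    Parameters
    ----------
    theta : mean of the selection-frequency variable, in (0, 1).
    x : tail threshold as a proportion in (0, 1].
    B : number of grid points minus one (number of fits).
    r : concavity index, r < 0 (``-1/2`` and ``-1/4`` are the standard
        choices for the pair-intersection and half-sample frequencies).

    Returns 1.0 when the threshold is too close to the mean for the
    extremal argument to be informative (x*B below ceil(2*theta*B)+1).
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must be in (0,1), got {theta}")
    if r >= 0:
        raise ValueError("r must be negative")
    i_min = int(math.ceil(x * B - 1e-9))
    if i_min <= 0:
        return 1.0
    if i_min > B:
        return 0.0
    if i_min < math.ceil(2.0 * theta * B) + 1:
        return 1.0  # outside the validity region of the tail bound
    s = 1.0 / r
    best = 0.0
    for k in range(i_min, B + 1):
        best = max(best, _extremal_tail(theta, i_min, B, s, k))
    return min(best, 1.0)


def pfer_bound(tau: float, q: float, p: int, B: int) -> ErrorBound:
    """Bound E[V] <= p*M(tau, q, p) for complementary-pairs stability selection.

    Evaluates every applicable branch of the bound family and keeps the
    minimum:

    * ``basic`` -- q^2 / (p^2 (2 tau - 1)) for tau > 1/2;
    * ``r=-1/2`` -- worst-case tail of the per-pair simultaneous-selection
      count (mean (q/p)^2, B pairs) at threshold 2 tau - 1;
    * ``r=-1/4`` -- worst-case tail of the selection frequency over all
      2B half-samples (mean q/p) at threshold tau.

    The selection rule counted by V is "frequency at least tau"; tau is
    meaningful on the grid of multiples of 1/(2B).
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0,1], got {tau}")
    if q <= 0 or p <= 0 or q > p:
        raise ValueError(f"require 0 < q <= p, got q={q}, p={p}")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    theta = q / p
    candidates: dict[str, float] = {}
    if tau > 0.5:
        candidates["basic"] = min(1.0, theta * theta / (2.0 * tau - 1.0))
        candidates["r-concave:-1/2"] = rconcave_tail(
            theta * theta, 2.0 * tau - 1.0, B, -0.5
        )
    candidates["r-concave:-1/4"] = rconcave_tail(theta, tau, 2 * B, -0.25)
    method = min(candidates, key=candidates.get)
    m = min(1.0, candidates[method])
    return ErrorBound(
        tau=tau,
        p=p,
        q=q,
        B=B,
        ev_bound=p * m,
        method=method,
        trivial_regime=tau <= theta,
        branches={k: p * min(1.0, v) for k, v in candidates.items()},
    )


def tau_for_pfer(target_ev: float, q: float, p: int, B: int) -> ErrorBound:
    """Smallest threshold tau whose E[V] bound is at or below ``target_ev``.

    Searches the grid of attainable selection frequencies
    {1/(2B), 2/(2B), ..., 1}; the bound is a step function constant
    between grid points, so the grid resolution is the natural one.
    Raises ``ValueError`` when even tau = 1 cannot reach the target.
    """
    if target_ev <= 0:
        raise ValueError(f"target_ev must be positive, got {target_ev}")
    n_grid = 2 * B
    # ev_bound is non-increasing in tau: bisect the grid index.
    lo, hi = 1, n_grid  # tau = lo/n_grid .. 1
    if pfer_bound(1.0, q, p, B).ev_bound > target_ev:
        raise ValueError(
            f"bound exceeds target {target_ev} even at tau=1; "
            "increase the target or reduce q"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if pfer_bound(mid / n_grid, q, p, B).ev_bound <= target_ev:
            hi = mid
        else:
            lo = mid + 1
    return pfer_bound(lo / n_grid, q, p, B)
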