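"""Group-LASSO solver: prox operator, optimality, CV, effect recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize

from groupscreen.design import Group, GroupedDesign
from groupscreen.solver import (
    PenaltyConfig,
    cv_select_lambda,
    fit,
    group_soft_threshold,
    kkt_violation,
    lambda_max,
    recover_effects,
)

from conftest import make_design


def reference_objective(X, y, sizes, lam1, lam2, w, seed_count=3):
    """Generic convex reference: minimize the same objective via SLSQP with
    cone splitting ||beta_j|| <= t_j (independent of the descent solver)."""
    n, p = X.shape
    bounds_groups = []
    s = 0
    for d in sizes:
        bounds_groups.append((s, s + d))
        s += d
    ngr = len(sizes)

    def obj(v):
        b, t = v[:p], v[p:]
        return (
            0.5 * np.sum((y - X @ b) ** 2) / n
            + lam1 * np.sum(w * t)
            + 0.5 * lam2 * np.sum(b**2)
        )

    cons = []
    for j, (a, e) in enumerate(bounds_groups):
        cons.append(
            {
                "type": "ineq",
                "fun": lambda v, a=a, e=e, j=j: v[p + j] ** 2 - np.sum(v[a:e] ** 2),
            }
        )
        cons.append({"type": "ineq", "fun": lambda v, j=j: v[p + j]})
    # informed but solver-independent start: the ridge solution
    ridge = np.linalg.solve(X.T @ X / n + (lam2 + 1e-3) * np.eye(p), X.T @ y / n)
    starts = [np.concatenate([ridge, np.ones(ngr)])]
    for trial in range(max(seed_count - 1, 0)):
        rng = np.random.default_rng(trial)
        starts.append(np.concatenate([rng.normal(0, 0.1, p), np.ones(ngr)]))
    def true_obj(b):
        t = np.array([np.linalg.norm(b[a:e]) for a, e in bounds_groups])
        return obj(np.concatenate([b, t]))

    best = np.inf
    for v0 in starts:
        res = minimize(
            obj, v0, method="SLSQP", constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        best = min(best, true_obj(res.x[:p]))

    # second independent route: smooth the group norms with
    # sqrt(||b_j||^2 + eps^2) and follow a continuation in eps with L-BFGS
    def smooth_obj(b, eps):
        val = 0.5 * np.sum((y - X @ b) ** 2) / n + 0.5 * lam2 * np.sum(b**2)
        grad = -X.T @ (y - X @ b) / n + lam2 * b
        for j, (a, e) in enumerate(bounds_groups):
            nrm = np.sqrt(np.sum(b[a:e] ** 2) + eps**2)
            val += lam1 * w[j] * (nrm - eps)
            grad[a:e] += lam1 * w[j] * b[a:e] / nrm
        return val, grad

    b = ridge.copy()
    for eps in (1e-3, 1e-6, 1e-9, 1e-12):
        res = minimize(
            smooth_obj, b, args=(eps,), jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-12},
        )
        b = res.x
    return min(best, true_obj(b))


class TestGroupSoftThreshold:
    def test_boundary_zeroes(self):
        assert (group_soft_threshold(np.array([3.0, 4.0]), 5.0) == 0).all()

    def test_zero_threshold_identity(self, rng):
        z = rng.normal(size=7)
        assert np.allclose(group_soft_threshold(z, 0.0), z)

    def test_shrinkage_formula(self):
        out = group_soft_threshold(np.array([3.0, 4.0]), 2.5)
        assert np.allclose(out, [1.5, 2.0])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            group_soft_threshold(np.ones(2), -1.0)


class TestFit:
    def test_ols_at_zero_penalty(self, rng):
        """Full-rank unpenalized limit equals least squares."""
        X = rng.normal(size=(60, 12))
        y = rng.normal(size=60)
        d = make_design(X, y, [1, 2, 3, 1, 5])
        res = fit(
            d,
            PenaltyConfig(
                lambda1=0.0, lambda2=0.0, tol=1e-14, kkt_tol=1e-10, max_sweeps=20000
            ),
        )
        bols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(res.beta, bols, rtol=1e-6, atol=1e-8)

    def test_all_zero_above_lambda_max(self, rng):
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        d = make_design(X, y, [2, 2, 3, 3])
        lmax = lambda_max(d)
        res = fit(d, PenaltyConfig(lambda1=lmax * 1.000001, lambda2=0.0))
        assert (res.beta == 0).all()
        assert res.active_groups == set()
        # and the zero solution is KKT-optimal
        assert kkt_violation(d, PenaltyConfig(lambda1=lmax * 1.000001, lambda2=0.0), res) <= 1e-10
        # just below lambda_max something activates
        res2 = fit(d, PenaltyConfig(lambda1=lmax * 0.999, lambda2=0.0))
        assert len(res2.active_groups) >= 1

    def test_orthonormal_one_sweep_closed_form(self, rng):
        """On a block-orthonormal design a single sweep lands exactly on
        group_soft_threshold(X_j^T y / n, lambda w_j)."""
        n, sizes = 40, [2, 3, 1, 5]
        p = sum(sizes)
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q[:, :p] * np.sqrt(n)  # X^T X = n I
        y = rng.normal(size=n)
        d = make_design(X, y, sizes)
        lam1 = 0.05
        res = fit(d, PenaltyConfig(lambda1=lam1, lambda2=0.0, max_sweeps=1),
                  check_kkt=False)
        s = 0
        for j, dsz in enumerate(sizes):
            closed = group_soft_threshold(
                X[:, s : s + dsz].T @ y / n, lam1 * np.sqrt(dsz)
            )
            assert np.allclose(res.beta[s : s + dsz], closed, atol=1e-8)
            s += dsz

    def test_objective_monotone_and_kkt(self, rng):
        X = rng.normal(size=(50, 14))
        y = X[:, 0] * 2 + rng.normal(size=50)
        d = make_design(X, y, [1, 1, 2, 2, 3, 5])
        pen = PenaltyConfig(lambda1=0.05, lambda2=0.01)
        res = fit(d, pen)
        assert np.all(np.diff(res.objective_history) <= 1e-12)
        assert res.converged
        assert res.kkt < 1e-6
        assert kkt_violation(d, pen, res) == pytest.approx(res.kkt, abs=1e-12)

    def test_all_or_none_group_sparsity(self, rng):
        X = rng.normal(size=(40, 12))
        y = rng.normal(size=40)
        d = make_design(X, y, [3, 3, 3, 3])
        res = fit(d, PenaltyConfig(lambda1=0.1, lambda2=0.0))
        for j, g in enumerate(d.groups):
            block = res.beta[g.start : g.end]
            assert (block == 0).all() or (block != 0).all()

    def test_matches_generic_convex_reference(self, rng):
        """Objective within 1e-6 of an independent constrained optimizer."""
        for trial in range(5):
            n = int(rng.integers(25, 50))
            sizes = []
            while sum(sizes) < 10:
                sizes.append(int(rng.integers(1, 5)))
            X = rng.normal(size=(n, sum(sizes)))
            y = rng.normal(size=n)
            lam1 = 10 ** rng.uniform(-2, -0.5)
            lam2 = float(rng.choice([0.0, 0.01]))
            d = make_design(X, y, sizes)
            res = fit(d, PenaltyConfig(lambda1=lam1, lambda2=lam2))
            w = np.sqrt(np.array(sizes, float))
            ref = reference_objective(X, y, sizes, lam1, lam2, w)
            assert res.objective <= ref + 1e-6
            assert res.kkt < 1e-6

    def test_beats_random_feasible_points(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.normal(size=30)
        sizes = [2, 2, 4]
        d = make_design(X, y, sizes)
        lam1 = 0.05
        res = fit(d, PenaltyConfig(lambda1=lam1, lambda2=0.0))
        w = np.repeat(np.sqrt([2, 2, 4]), [2, 2, 4])
        gidx = np.repeat([0, 1, 2], [2, 2, 4])
        B = rng.normal(scale=0.5, size=(10_000, 8))
        B[:: 3] = 0.0  # include sparse candidates
        r = y[None, :] - B @ X.T
        rss = 0.5 * (r**2).sum(axis=1) / 30
        norms = np.zeros((10_000, 3))
        for j in range(3):
            norms[:, j] = np.linalg.norm(B[:, gidx == j], axis=1)
        objs = rss + lam1 * (np.sqrt([2, 2, 4]) * norms).sum(axis=1)
        assert res.objective <= objs.min() + 1e-12

    def test_elastic_net_unique_with_duplicate_columns(self, rng):
        """Identical columns in different groups: the ridge term makes the
        optimum unique, so different starts agree."""
        x = rng.normal(size=40)
        X = np.column_stack([x, x, rng.normal(size=40)])
        y = x * 1.5 + rng.normal(scale=0.1, size=40)
        d = make_design(X, y, [1, 1, 1])
        pen = PenaltyConfig(lambda1=0.02, lambda2=0.05)
        r1 = fit(d, pen)
        r2 = fit(d, pen, beta0=rng.normal(size=3))
        assert np.allclose(r1.beta, r2.beta, atol=1e-5)

    def test_lambda_path_active_count_monotone_orthonormal(self, rng):
        n, sizes = 60, [2, 2, 2, 2, 2]
        p = sum(sizes)
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q[:, :p] * np.sqrt(n)
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        d = make_design(X, y, sizes)
        counts = []
        for lam in np.geomspace(lambda_max(d), 1e-3, 12):
            res = fit(d, PenaltyConfig(lambda1=float(lam), lambda2=0.0))
            counts.append(len(res.active_groups))
        assert np.all(np.diff(counts) >= 0)

    def test_nonfinite_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[0, 0] = np.nan
        d = make_design(X, np.zeros(10), [1, 1])
        with pytest.raises(ValueError, match="finite"):
            fit(d, PenaltyConfig(lambda1=0.1))

    def test_kkt_increases_under_perturbation(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] + rng.normal(size=40)
        d = make_design(X, y, [2, 2, 2])
        pen = PenaltyConfig(lambda1=0.05, lambda2=0.0)
        res = fit(d, pen)
        base = kkt_violation(d, pen, res)
        if res.active_groups:
            j = min(res.active_groups)
            g = d.groups[j]
            import dataclasses

            pert = dataclasses.replace(res, beta=res.beta.copy())
            pert.beta[g.start] += 0.1
            assert kkt_violation(d, pen, pert) > base


class TestCV:
    def test_single_lambda_grid(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        d = make_design(X, y, [2, 2, 2])
        lam, errs, grid = cv_select_lambda(d, lambda_grid_values=np.array([0.3]), folds=4)
        assert lam == 0.3 and len(errs) == 1

    def test_nonpositive_grid_rejected(self, rng):
        d = make_design(rng.normal(size=(20, 2)), np.zeros(20), [1, 1])
        with pytest.raises(ValueError, match="positive"):
            cv_select_lambda(d, lambda_grid_values=np.array([0.5, 0.0]))

    def test_fold_partition(self, rng):
        """Every sample lands in exactly one validation fold."""
        n, folds = 53, 5
        rng2 = np.random.default_rng(9)
        perm = rng2.permutation(n)
        ids = np.empty(n, dtype=int)
        for k, chunk in enumerate(np.array_split(perm, folds)):
            ids[chunk] = k
        assert np.bincount(ids, minlength=folds).sum() == n
        assert set(np.unique(ids)) == set(range(folds))

    def test_null_outcome_prefers_heavy_penalty(self, rng):
        """With pure-noise outcomes CV deactivates nearly all groups."""
        deactivated = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(80, 30))
            y = r.normal(size=80)
            d = make_design(X, y, [1] * 30)
            lam, _, _ = cv_select_lambda(d, folds=5, seed=seed)
            res = fit(d, PenaltyConfig(lambda1=lam))
            deactivated.append(1 - len(res.active_groups) / 30)
        assert np.median(deactivated) >= 0.95


class TestRecoverEffects:
    def test_overlapped_sum_and_scale_unwinding(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        X = np.column_stack([x1, x1, x2])
        d = GroupedDesign(
            X=X,
            y=x1 * 2.0,
            groups=[
                Group("a", 0, 1, 1.0, "cpg", (0,)),
                Group("b", 1, 3, np.sqrt(2), "interaction", (0, 1)),
            ],
            duplication_map={0: ("cpg", 0), 1: ("cpg", 0), 2: ("snp", 1, 1)},
            scales=np.array([1.0, 2.0, 1.0]),
        )
        res = fit(d, PenaltyConfig(lambda1=1e-4, lambda2=1e-6))
        eff = recover_effects(res, d)
        # column 1 is column 0 at half scale: total effect ~ 2.0
        assert eff[("cpg", 0)] == pytest.approx(
            res.beta[0] + res.beta[1] / 2.0, abs=1e-12
        )
        assert eff[("cpg", 0)] == pytest.approx(2.0, rel=0.05)

    def test_missing_column_rejected(self, rng):
        d = make_design(rng.normal(size=(20, 2)), np.zeros(20), [1, 1])
        d.duplication_map = {0: ("cpg", 0)}  # column 1 unregistered
        res = fit(d, PenaltyConfig(lambda1=0.1))
        with pytest.raises(KeyError):
            recover_effects(res, d)

    def test_single_column_identity(self, rng):
        X = rng.normal(size=(25, 2))
        d = make_design(X, X[:, 0], [1, 1])
        d.duplication_map = {0: ("cpg", 0), 1: ("cpg", 1)}
        res = fit(d, PenaltyConfig(lambda1=0.01))
        eff = recover_effects(res, d)
        assert eff[("cpg", 0)] == pytest.approx(res.beta[0])
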