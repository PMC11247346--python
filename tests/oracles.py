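"""Independent numerical oracles for the penalized-regression tests.

The sparse-group objective is nonsmooth, so the oracles minimize an
equivalent smooth program obtained by variable splitting: beta = p - q
with p, q >= 0 (so ||beta||_1 = sum(p + q) at the optimum) and one
auxiliary t_g per group constrained by t_g^2 >= ||p_g - q_g||^2 (so
t_g = ||beta_g||_2 at the optimum).  The reformulation is solved with
scipy's general constrained optimizers from multiple starts; these
routines share no code with the proximal-gradient solver they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize


def _split_objective(X, y, w, alpha_site, alpha_group, group_ranges, gweights):
    n, p = X.shape
    n_groups = len(group_ranges)

    def unpack(z):
        beta0 = z[0]
        beta = z[1 : 1 + p] - z[1 + p : 1 + 2 * p]
        t = z[1 + 2 * p :]
        return beta0, beta, t

    def fun(z):
        beta0, beta, t = unpack(z)
        margin = y * (beta0 + X @ beta)
        loss = np.sum(w * np.logaddexp(0.0, -margin)) / n
        l1 = alpha_site * np.sum(z[1 : 1 + 2 * p])
        grp = alpha_group * np.sum(gweights * t)
        return loss + l1 + grp

    def group_con(z):
        _, beta, t = unpack(z)
        return np.array(
            [
                t[gi] ** 2 - float(beta[a:b] @ beta[a:b])
                for gi, (a, b) in enumerate(group_ranges)
            ]
        )

    return fun, group_con, n_groups


def sgl_logistic_optimum(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    alpha_site: float,
    alpha_group: float,
    group_ranges: list[tuple[int, int]],
    gweights: np.ndarray,
    target: float | None = None,
    target_tol: float = 1e-7,
) -> float:
    """Optimal penalized weighted logistic objective, by generic solvers.

    SLSQP runs first from two starts; the slower trust-constr pass is
    added only when the SLSQP optimum has not already been located to
    within ``target_tol`` of ``target`` (an optional short-circuit — the
    search itself never uses the target).
    """
    n, p = X.shape
    n_groups = len(group_ranges)
    fun, group_con, _ = _split_objective(
        X, y, w, alpha_site, alpha_group, group_ranges, gweights
    )
    nvar = 1 + 2 * p + n_groups
    bounds = [(None, None)] + [(0, None)] * (2 * p) + [(0, None)] * n_groups
    con = NonlinearConstraint(group_con, 0, np.inf)

    starts = [np.zeros(nvar)]
    rng = np.random.default_rng(0)
    s = 0.1 * rng.standard_normal(nvar)
    s[1:] = np.abs(s[1:])
    starts.append(s)

    def polish(r):
        # recompute the objective with exact group norms
        beta0 = r.x[0]
        beta = r.x[1 : 1 + p] - r.x[1 + p : 1 + 2 * p]
        margin = y * (beta0 + X @ beta)
        loss = np.sum(w * np.logaddexp(0.0, -margin)) / n
        pen = alpha_site * np.sum(np.abs(beta)) + alpha_group * np.sum(
            gweights * [np.linalg.norm(beta[a:b]) for a, b in group_ranges]
        )
        return loss + pen

    best = np.inf
    attempts = [("SLSQP", x0) for x0 in starts] + [
        ("trust-constr", x0) for x0 in starts
    ]
    for method, x0 in attempts:
        if (
            method == "trust-constr"
            and target is not None
            and np.isfinite(best)
            and abs(best - target) <= target_tol * max(1.0, abs(target))
        ):
            break
        opts = (
            {"maxiter": 500, "ftol": 1e-14}
            if method == "SLSQP"
            else {"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14}
        )
        try:
            r = minimize(
                fun, x0, method=method, bounds=bounds, constraints=[con],
                options=opts,
            )
        except Exception:
            continue
        if np.isfinite(r.fun):
            best = min(best, polish(r))
    return float(best)


def prox_objective(u, v, step, alpha_site, alpha_group, group_ranges, gweights):
    pen = alpha_site * np.sum(np.abs(u)) + alpha_group * np.sum(
        gweights * [np.linalg.norm(u[a:b]) for a, b in group_ranges]
    )
    return 0.5 * float((u - v) @ (u - v)) + step * pen


def prox_optimum(
    v: np.ndarray,
    step: float,
    alpha_site: float,
    alpha_group: float,
    group_ranges: list[tuple[int, int]],
    gweights: np.ndarray,
) -> float:
    """Minimum of the prox-defining objective, by generic solvers."""
    p = len(v)
    n_groups = len(group_ranges)

    def unpack(z):
        return z[:p] - z[p : 2 * p], z[2 * p :]

    def fun(z):
        u, t = unpack(z)
        return (
            0.5 * float((u - v) @ (u - v))
            + step * alpha_site * np.sum(z[: 2 * p])
            + step * alpha_group * float(gweights @ t)
        )

    def group_con(z):
        u, t = unpack(z)
        return np.array(
            [
                t[gi] ** 2 - float(u[a:b] @ u[a:b])
                for gi, (a, b) in enumerate(group_ranges)
            ]
        )

    nvar = 2 * p + n_groups
    bounds = [(0, None)] * nvar
    con = NonlinearConstraint(group_con, 0, np.inf)
    x0 = np.concatenate([np.clip(v, 0, None), np.clip(-v, 0, None), np.ones(n_groups)])
    best = np.inf
    # strongly convex: SLSQP alone suffices; trust-constr is the fallback
    for method in ("SLSQP", "trust-constr"):
        opts = (
            {"maxiter": 500, "ftol": 1e-14}
            if method == "SLSQP"
            else {"maxiter": 2000, "gtol": 1e-12, "xtol": 1e-14}
        )
        try:
            r = minimize(
                fun, x0, method=method, bounds=bounds, constraints=[con],
                options=opts,
            )
        except Exception:
            continue
        if np.isfinite(r.fun):
            u, _ = unpack(r.x)
            best = min(
                best,
                prox_objective(u, v, step, alpha_site, alpha_group,
                               group_ranges, gweights),
            )
            if method == "SLSQP" and r.success:
                break
    return float(best)


def random_tiny_dataset(rng, n=10, n_groups=2, cols_per_group=3):
    """A tiny grouped 0/1 design with both classes present."""
    from cladesparse.alignment import EncodedDataset
    import pandas as pd

    p = n_groups * cols_per_group
    X = (rng.random((n, p)) < 0.5).astype(float)
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    y[0], y[1] = 1.0, -1.0  # both classes
    group_map = {
        f"g{k}": (k * cols_per_group, (k + 1) * cols_per_group)
        for k in range(n_groups)
    }
    meta = pd.DataFrame(
        [
            (f"g{j // cols_per_group}", j % cols_per_group, "A")
            for j in range(p)
        ],
        columns=["gene", "site", "residue"],
    )
    return EncodedDataset(
        X=X,
        group_map=group_map,
        taxon_order=[f"t{i}" for i in range(n)],
        y=y,
        missing_mask=np.zeros((n, n_groups), dtype=bool),
        column_meta=meta,
    )
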