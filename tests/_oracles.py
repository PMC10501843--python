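"""Independent oracles used by the tests.

The projection oracle solves min ||w - x||^2 over a constraint set with a
generic smooth convex-programming routine (SLSQP), entirely independent of
the closed-form projections it is used to check.  The L1 ball is handled
through the standard positive/negative splitting so the constraint stays
smooth.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import LinearConstraint, NonlinearConstraint, minimize

_OPTS = {"maxiter": 1000, "ftol": 1e-12}


def _feasible(z, constraints, bounds, tol=1e-9):
    ok = all(np.min(c["fun"](z)) >= -tol for c in constraints)
    if bounds is not None:
        ok = ok and np.all(z >= -tol)
    return ok


def _slsqp(x0, objective, jac, constraints, bounds=None):
    """SLSQP solve followed by a polishing pass; trust-constr as backup.

    Success is judged by feasibility of the returned point, not the status
    flag (SLSQP occasionally reports a line-search stall at the optimum).
    """
    best = None
    x_cur = np.asarray(x0, float)
    for opts in (_OPTS, {"maxiter": 400, "ftol": 1e-16}):
        res = minimize(
            objective, x_cur, jac=jac, method="SLSQP",
            bounds=bounds, constraints=constraints, options=opts,
        )
        if _feasible(res.x, constraints, bounds) and (
            best is None or objective(res.x) < objective(best)
        ):
            best = res.x
        x_cur = res.x
    nlcs = [NonlinearConstraint(c["fun"], 0.0, np.inf, jac=c["jac"]) for c in constraints]
    res2 = minimize(
        objective, x0, jac=jac, method="trust-constr",
        bounds=bounds, constraints=nlcs,
        options={"gtol": 1e-12, "xtol": 1e-16, "maxiter": 3000},
    )
    if _feasible(res2.x, constraints, bounds) and (
        best is None or objective(res2.x) < objective(best)
    ):
        best = res2.x
    if best is None:
        raise RuntimeError("oracle failed: no feasible solution found")
    return best


def qp_project_halfspace(x, a, b):
    """min ||w - x||^2 s.t. <a, w> <= b via SLSQP."""
    x = np.asarray(x, float)
    a = np.asarray(a, float)
    cons = [{"type": "ineq", "fun": lambda w: b - a @ w, "jac": lambda w: -a}]
    return _slsqp(
        x - max(a @ x - b, 0) * 0.1 * a,  # start mildly toward feasibility
        lambda w: float((w - x) @ (w - x)),
        lambda w: 2.0 * (w - x),
        cons,
    )


def qp_project_ball(x, center, radius):
    """min ||w - x||^2 s.t. ||w - center||^2 <= radius^2 via SLSQP."""
    x = np.asarray(x, float)
    center = np.asarray(center, float)
    cons = [{
        "type": "ineq",
        "fun": lambda w: radius**2 - (w - center) @ (w - center),
        "jac": lambda w: -2.0 * (w - center),
    }]
    d = x - center
    x0 = center + 0.5 * d if np.linalg.norm(d) > radius else x
    return _slsqp(
        x0,
        lambda w: float((w - x) @ (w - x)),
        lambda w: 2.0 * (w - x),
        cons,
    )


def qp_project_l1_ball(x, gamma):
    """min ||p - q - x||^2 s.t. sum(p + q) <= gamma, p, q >= 0 via SLSQP."""
    x = np.asarray(x, float)
    d = x.size
    ones = np.ones(2 * d)

    def obj(z):
        w = z[:d] - z[d:]
        return float((w - x) @ (w - x))

    def jac(z):
        w = z[:d] - z[d:]
        g = 2.0 * (w - x)
        return np.concatenate([g, -g])

    cons = [{"type": "ineq", "fun": lambda z: gamma - ones @ z, "jac": lambda z: -ones}]
    z0 = np.concatenate([np.maximum(x, 0), np.maximum(-x, 0)])
    if z0.sum() > gamma:
        z0 *= gamma / z0.sum()
    z = _slsqp(z0, obj, jac, cons, bounds=[(0, None)] * (2 * d))
    w = z[:d] - z[d:]
    # active-set polish: refine the support identified by the generic solver
    # through the reduced KKT system (budget active, w_i = x_i - theta*sign)
    if np.abs(x).sum() > gamma + 1e-12:
        support = np.abs(w) > 1e-8
        if support.any():
            theta = (np.abs(x[support]).sum() - gamma) / support.sum()
            if theta >= 0 and np.all(np.abs(x[support]) - theta > 0):
                w_ref = np.zeros(d)
                w_ref[support] = np.sign(x[support]) * (np.abs(x[support]) - theta)
                if (
                    np.abs(w_ref).sum() <= gamma + 1e-10
                    and (w_ref - x) @ (w_ref - x) <= (w - x) @ (w - x) + 1e-9
                ):
                    w = w_ref
    return w


def _kkt_polish(x, h, grad_h, hess_h, w0, iters=60):
    """Newton refinement of min ||w-x||^2 s.t. h(w) <= 0 for one smooth h.

    Solves the stationarity system 2(w-x) + mu*grad_h(w) = 0, h(w) = 0 from
    an approximate active solution; returns None if Newton leaves the
    active regime (mu <= 0), in which case the caller keeps its iterate.
    """
    x = np.asarray(x, float)
    if h(x) <= 0:
        return x.copy()
    w = np.asarray(w0, float).copy()
    mu = 2.0 * np.linalg.norm(w - x) / max(np.linalg.norm(grad_h(w)), 1e-12)
    d = x.size
    for _ in range(iters):
        q = grad_h(w)
        F = np.concatenate([2.0 * (w - x) + mu * q, [h(w)]])
        if np.linalg.norm(F) < 1e-13:
            break
        J = np.zeros((d + 1, d + 1))
        J[:d, :d] = 2.0 * np.eye(d) + mu * hess_h(w)
        J[:d, d] = q
        J[d, :d] = q
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        w += step[:d]
        mu += step[d]
    if mu < 0 or abs(h(w)) > 1e-10:
        return None
    return w


def qp_project_relaxed(x, S):
    """Projection onto a relaxed set via its raw membership inequality."""
    x = np.asarray(x, float)
    anchor, g, fval, kappa = S.anchor, S.subgrad, S.fval, S.curvature

    def membership(w):
        d = anchor - w
        return -(fval - g @ d + 0.5 * kappa * (d @ d))

    def membership_jac(w):
        d = anchor - w
        return kappa * d - g  # d/dw of -(fval - g.d + k/2 d.d)

    cons = [{"type": "ineq", "fun": membership, "jac": membership_jac}]
    if membership(x) >= 0:
        x0 = x
    elif kappa > 0:
        x0 = anchor - g / kappa  # ball center, strictly feasible
    else:
        x0 = x - (g / max(g @ g, 1e-12)) * (fval - g @ (anchor - x))
    w = _slsqp(
        x0,
        lambda w: float((w - x) @ (w - x)),
        lambda w: 2.0 * (w - x),
        cons,
    )
    # the generic solvers land ~1e-6 inside the boundary; polish the KKT system
    polished = _kkt_polish(
        x,
        h=lambda w: -membership(w),
        grad_h=lambda w: -membership_jac(w),
        hess_h=lambda w: kappa * np.eye(x.size),
        w0=w,
    )
    if polished is not None and membership(polished) >= -1e-9:
        obj = lambda v: float((v - x) @ (v - x))
        if obj(polished) <= obj(w) + 1e-9:
            return polished
    return w


def finite_diff_grad(f, x, h=1e-6):
    """Central-difference gradient of a scalar function."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g
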