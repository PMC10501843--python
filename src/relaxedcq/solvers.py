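"""Projection algorithms for the split feasibility problem.

Four iteration schemes over a common interface:

``imrcqm``
    The inertial modified relaxed CQ Mann scheme.  One iteration runs an
    inertial extrapolation, two relaxed gradient steps (at the extrapolated
    point and again at the intermediate point), a projection onto the
    relaxed C-set, and a Mann convex-averaging step.
``dang``
    Inertial relaxed CQ: inertial extrapolation followed by a single
    relaxed projected-gradient step with a fixed step size, using the
    capped extrapolation schedule min(sigma, 1/max(n^2 d^2, n^2 d)).
``igrcq``
    Inertial generalized relaxed CQ with the self-adaptive step
    eps * f_n / ||grad f_n||^2, which needs no operator-norm estimate.
``byrne``
    The classic CQ baseline with exact projections onto C and Q.

All relaxed schemes share the split-residual f_n(x) = 0.5*||(I - P_{Q_n})Ax||^2
with gradient A^T (I - P_{Q_n}) A x; driving f to zero solves the problem.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .geometry import (
    RelaxedSet,
    SFPInstance,
    build_relaxed_set,
    operator_norm_sq,
    project_relaxed,
)

__all__ = [
    "Method",
    "SolverConfig",
    "SolverRun",
    "grad_f",
    "sigma_schedule",
    "dang_sigma",
    "igrcq_stepsize",
    "imrcqm_step",
    "solve",
]


class Method(str, Enum):
    IMRCQM = "imrcqm"
    DANG = "dang"
    IGRCQ = "igrcq"
    BYRNE = "byrne"


@dataclass
class SolverConfig:
    """Parameters shared by all four schemes.

    Attributes
    ----------
    sigma : float in [0, 1)
        Base extrapolation factor.  Default 0.9999.
    lambda_rel : float in (0, 2)
        Relative step size; the actual step is lambda_rel / ||A||^2, which
        keeps it strictly inside the admissible (0, 2/||A||^2) window.
    alpha_mann : float in (0, 1)
        Mann averaging weight (imrcqm only).  Default 1/1.2.
    epsilon_n : float in (0, 4)
        Self-adaptive step factor (igrcq only).  Default 0.1.
    curvature_c, curvature_q : float >= 0
        Curvatures of the generalized relaxed sets (0 recovers plain
        half-space relaxations).
    decay_start : int >= 0
        Iteration after which the extrapolation decay branch is active.
        0 means always (required for the summability condition on
        sigma_n * max(||d||^2, ||d||)).
    igrcq_step_anchor : {"rho", "omega"}
        Where the self-adaptive step evaluates f and its gradient.  "rho"
        matches the gradient actually used by the update; "omega" is the
        literal printed form.
    """

    sigma: float = 0.9999
    lambda_rel: float = 0.9999
    alpha_mann: float = 1.0 / 1.2
    epsilon_n: float = 0.1
    curvature_c: float = 0.0
    curvature_q: float = 0.0
    max_iter: int = 5000
    tol: float = 1e-10
    decay_start: int = 0
    igrcq_step_anchor: str = "rho"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma < 1.0:
            raise ValueError("sigma must lie in [0, 1)")
        if not 0.0 < self.lambda_rel < 2.0:
            raise ValueError("lambda_rel must lie in (0, 2)")
        if not 0.0 < self.alpha_mann < 1.0:
            raise ValueError("alpha_mann must lie in (0, 1)")
        if not 0.0 < self.epsilon_n < 4.0:
            raise ValueError("epsilon_n must lie in (0, 4)")
        if self.curvature_c < 0 or self.curvature_q < 0:
            raise ValueError("curvatures must be nonnegative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.igrcq_step_anchor not in ("rho", "omega"):
            raise ValueError("igrcq_step_anchor must be 'rho' or 'omega'")


@dataclass
class IterRecord:
    """Per-iteration bookkeeping for one solver step."""

    n: int
    sigma_n: float
    lambda_n: float
    residual: float
    rho: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None
    dist_to_solution: Optional[float] = None


@dataclass
class SolverRun:
    """Full history of one solver invocation."""

    method: Method
    iterates: list[np.ndarray] = field(default_factory=list)
    aux: list[IterRecord] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    dist_to_solution: list[float] = field(default_factory=list)
    stop_reason: str = "max_iter"
    n_iter: int = 0
    elapsed: float = 0.0

    @property
    def final(self) -> np.ndarray:
        return self.iterates[-1]

    def trace_array(self) -> np.ndarray:
        """Columns: n, sigma_n, lambda_n, residual, dist-to-solution (nan if unknown)."""
        rows = [
            (
                r.n,
                r.sigma_n,
                r.lambda_n,
                r.residual,
                np.nan if r.dist_to_solution is None else r.dist_to_solution,
            )
            for r in self.aux
        ]
        return np.asarray(rows, dtype=float)


def grad_f(A: np.ndarray, Qrelax: RelaxedSet, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Split residual and its gradient with respect to a relaxed Q-set.

    Returns ``(f, grad)`` with ``f = 0.5 * ||(I - P_{Q_n}) A x||^2`` and
    ``grad = A^T (I - P_{Q_n}) A x``.
    """
    Ax = A @ x
    resid = Ax - project_relaxed(Ax, Qrelax)
    return 0.5 * float(resid @ resid), A.T @ resid


def sigma_schedule(
    sigma: float, n: int, delta: np.ndarray, N: int = 0
) -> float:
    """Decaying extrapolation factor.

    On the decay branch (past iteration ``N`` with a nonzero displacement
    ``delta = w_n - w_{n-1}``) returns ``sigma / (n^2 * max(||d||^2, ||d||))``,
    which makes sigma_n * max(||d||^2, ||d||) summable (bounded by
    sigma * pi^2/6); otherwise returns ``sigma`` unchanged.
    """
    nd = float(np.linalg.norm(delta))
    if n > N and nd != 0.0:
        return sigma / (n * n * max(nd * nd, nd))
    return sigma


def dang_sigma(sigma: float, n: int, delta: np.ndarray) -> float:
    """Capped extrapolation factor min(sigma, 1 / max(n^2 d^2, n^2 d))."""
    nd = float(np.linalg.norm(delta))
    if nd == 0.0:
        return sigma
    return min(sigma, 1.0 / max(n * n * nd * nd, n * n * nd))


def igrcq_stepsize(f_val: float, grad: np.ndarray, epsilon_n: float) -> float:
    """Self-adaptive step ``eps * f / ||grad||^2``; zero when the gradient vanishes."""
    g2 = float(grad @ grad)
    if g2 == 0.0:
        return 0.0
    return epsilon_n * f_val / g2


def _lambda_fixed(problem: SFPInstance, config: SolverConfig) -> float:
    return config.lambda_rel / operator_norm_sq(problem.A)


def imrcqm_step(
    omega_n: np.ndarray,
    omega_prev: np.ndarray,
    problem: SFPInstance,
    config: SolverConfig,
    n: int,
    lambda_n: Optional[float] = None,
) -> tuple[np.ndarray, IterRecord]:
    """One inertial modified relaxed CQ Mann iteration.

    Order of operations: extrapolation sigma_n and rho_n; relaxed Q-set
    anchored at A rho_n; gradient step y_n = rho_n - lambda * grad f(rho_n);
    relaxed C-set anchored at y_n; second gradient step t_n (same Q-set);
    projection z_n onto the relaxed C-set; Mann average of y_n and z_n.
    """
    A = problem.A
    if lambda_n is None:
        lambda_n = _lambda_fixed(problem, config)
    delta = omega_n - omega_prev
    sig_n = sigma_schedule(config.sigma, n, delta, config.decay_start)
    rho = omega_n + sig_n * delta

    Qn = build_relaxed_set(problem.Qset, A @ rho, config.curvature_q)
    f_rho, g_rho = grad_f(A, Qn, rho)
    y = rho - lambda_n * g_rho

    Cn = build_relaxed_set(problem.Cset, y, config.curvature_c)
    f_y, g_y = grad_f(A, Qn, y)
    t = y - lambda_n * g_y
    z = project_relaxed(t, Cn)

    # algebraically (1-a)y + az; this form is exact when z == y, which keeps
    # a solution an exact fixed point (the extrapolation schedule compares
    # ||w_n - w_{n-1}|| to zero exactly, so one ulp of drift would re-arm it)
    omega_next = y + config.alpha_mann * (z - y)
    if not np.all(np.isfinite(omega_next)):
        raise FloatingPointError("iterate diverged to non-finite values")
    rec = IterRecord(
        n=n, sigma_n=sig_n, lambda_n=lambda_n, residual=f_y, rho=rho, y=y, z=z
    )
    return omega_next, rec


def _dang_step(omega_n, omega_prev, problem, config, n, lambda_n):
    A = problem.A
    delta = omega_n - omega_prev
    sig_n = dang_sigma(config.sigma, n, delta)
    rho = omega_n + sig_n * delta
    Qn = build_relaxed_set(problem.Qset, A @ rho, config.curvature_q)
    f_rho, g_rho = grad_f(A, Qn, rho)
    Cn = build_relaxed_set(problem.Cset, rho, config.curvature_c)
    omega_next = project_relaxed(rho - lambda_n * g_rho, Cn)
    rec = IterRecord(n=n, sigma_n=sig_n, lambda_n=lambda_n, residual=f_rho, rho=rho)
    return omega_next, rec


def _igrcq_step(omega_n, omega_prev, problem, config, n):
    A = problem.A
    delta = omega_n - omega_prev
    sig_n = sigma_schedule(config.sigma, n, delta, config.decay_start)
    rho = omega_n + sig_n * delta
    Qn = build_relaxed_set(problem.Qset, A @ rho, config.curvature_q)
    f_rho, g_rho = grad_f(A, Qn, rho)
    if config.igrcq_step_anchor == "rho":
        lam = igrcq_stepsize(f_rho, g_rho, config.epsilon_n)
    else:
        f_om, g_om = grad_f(A, Qn, omega_n)
        lam = igrcq_stepsize(f_om, g_om, config.epsilon_n)
    Cn = build_relaxed_set(problem.Cset, rho, config.curvature_c)
    omega_next = project_relaxed(rho - lam * g_rho, Cn)
    rec = IterRecord(n=n, sigma_n=sig_n, lambda_n=lam, residual=f_rho, rho=rho)
    return omega_next, rec


def _byrne_step(omega_n, problem, config, n, lambda_n):
    A = problem.A
    Aw = A @ omega_n
    resid = Aw - problem.Qset.project(Aw)
    f_val = 0.5 * float(resid @ resid)
    omega_next = problem.Cset.project(omega_n - lambda_n * (A.T @ resid))
    rec = IterRecord(n=n, sigma_n=0.0, lambda_n=lambda_n, residual=f_val)
    return omega_next, rec


def solve(
    problem: SFPInstance,
    method: Method | str = Method.IMRCQM,
    config: Optional[SolverConfig] = None,
    omega0: Optional[np.ndarray] = None,
    keep_iterates: bool = True,
) -> SolverRun:
    """Run one scheme on an SFP instance until the residual drops below tol.

    The residual monitored is the split residual f at the point where the
    scheme evaluates its gradient (y_n for imrcqm, rho_n for the inertial
    comparison schemes, omega_n for the classic baseline).  Iteration stops
    at the first residual <= tol or after max_iter steps.

    With ``omega0`` omitted the start is the zero vector, which is interior
    to every origin-centered norm ball.
    """
    method = Method(method)
    if config is None:
        config = SolverConfig()
    n_dim = problem.A.shape[1]
    if omega0 is None:
        omega0 = np.zeros(n_dim)
    omega0 = np.asarray(omega0, dtype=float)
    if omega0.shape != (n_dim,):
        raise ValueError(f"omega0 must have shape ({n_dim},)")

    w_star = problem.known_solution
    lam_fixed = (
        _lambda_fixed(problem, config) if method is not Method.IGRCQ else None
    )

    run = SolverRun(method=method)
    t0 = time.perf_counter()
    omega_prev = omega0.copy()
    omega_n = omega0.copy()
    run.iterates.append(omega_n.copy())
    stop = "max_iter"
    for n in range(1, config.max_iter + 1):
        if method is Method.IMRCQM:
            omega_next, rec = imrcqm_step(
                omega_n, omega_prev, problem, config, n, lam_fixed
            )
        elif method is Method.DANG:
            omega_next, rec = _dang_step(
                omega_n, omega_prev, problem, config, n, lam_fixed
            )
        elif method is Method.IGRCQ:
            omega_next, rec = _igrcq_step(omega_n, omega_prev, problem, config, n)
        else:
            omega_next, rec = _byrne_step(omega_n, problem, config, n, lam_fixed)
        if not np.all(np.isfinite(omega_next)):
            raise FloatingPointError("iterate diverged to non-finite values")
        if w_star is not None:
            rec.dist_to_solution = float(np.linalg.norm(omega_next - w_star))
            run.dist_to_solution.append(rec.dist_to_solution)
        if not keep_iterates:
            rec.rho = rec.y = rec.z = None
        run.aux.append(rec)
        run.residuals.append(rec.residual)
        if keep_iterates:
            run.iterates.append(omega_next.copy())
        else:
            run.iterates = [omega_next.copy()]
        omega_prev, omega_n = omega_n, omega_next
        run.n_iter = n
        # tol = 0 disables the residual stop: the relaxed residual can hit
        # exactly zero at a point that is not a solution (a large step can
        # land inside the current half-space relaxation)
        if config.tol > 0 and rec.residual <= config.tol:
            stop = "tol_reached"
            break
    run.stop_reason = stop
    run.elapsed = time.perf_counter() - t0
    return run
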