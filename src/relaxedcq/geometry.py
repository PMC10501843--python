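"""Constraint sets, closed-form projections, and per-iteration relaxations.

The split feasibility problem works with two closed convex sets, each given
as a sublevel set of a convex function: ``C = {w : c(w) <= 0}`` and
``Q = {v : q(v) <= 0}``.  Relaxed CQ algorithms never project onto ``C`` or
``Q`` directly; at each iteration they build a superset from the function
value and one subgradient at an anchor point.  With zero curvature the
superset is a half-space; with positive curvature it tightens to a ball
(obtained by completing the square) while still containing the true set.

All projections here are exact closed forms, which is the entire point of
the relaxation: the per-iteration sets are cheap to project onto even when
``C`` and ``Q`` are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "ConvexConstraint",
    "RelaxedSet",
    "SFPInstance",
    "EmptySetError",
    "operator_norm_sq",
    "project_halfspace",
    "project_ball",
    "project_l1_ball",
    "build_relaxed_set",
    "project_relaxed",
    "l1_ball_constraint",
    "l2_ball_constraint",
    "halfspace_constraint",
    "singleton_constraint",
    "box_constraint",
    "make_constraint",
]


class EmptySetError(ValueError):
    """Raised when a (relaxed) constraint set is empty.

    An empty relaxation signals an invalid curvature choice and is a hard
    error rather than a silent skip.
    """


@dataclass(frozen=True)
class ConvexConstraint:
    """A closed convex set described by a convex function and its subgradient.

    Parameters
    ----------
    value_oracle
        Convex function ``c`` whose 0-sublevel set is the constraint.
    subgrad_oracle
        Returns one element of the subdifferential of ``c`` at a point.
        For differentiable instances this is the gradient.
    label
        Human-readable tag (``"l1_ball"``, ``"l2_ball"``, ...).
    projector
        Optional exact Euclidean projection onto the true set, available
        for the standard constraint kinds.  Needed by the classic CQ
        iteration, which projects onto the true sets; the relaxed methods
        never call it.
    """

    value_oracle: Callable[[np.ndarray], float]
    subgrad_oracle: Callable[[np.ndarray], np.ndarray]
    label: str = "constraint"
    projector: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def value(self, x: np.ndarray) -> float:
        return float(self.value_oracle(np.asarray(x, dtype=float)))

    def subgrad(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.subgrad_oracle(np.asarray(x, dtype=float)), dtype=float)

    def contains(self, x: np.ndarray, tol: float = 0.0) -> bool:
        return self.value(x) <= tol

    def project(self, x: np.ndarray) -> np.ndarray:
        if self.projector is None:
            raise NotImplementedError(
                f"no exact projector available for constraint {self.label!r}"
            )
        return np.asarray(self.projector(np.asarray(x, dtype=float)), dtype=float)


@dataclass(frozen=True)
class RelaxedSet:
    """One iteration's relaxation of a constraint set.

    Membership is the inequality

        fval <= <subgrad, anchor - w> - (curvature/2) * ||anchor - w||^2,

    a half-space when ``curvature == 0`` and a ball when ``curvature > 0``.
    Every point of the true set belongs to the relaxation (by convexity of
    the defining function), so projecting onto it never overshoots the
    feasible region.
    """

    anchor: np.ndarray
    fval: float
    subgrad: np.ndarray
    curvature: float = 0.0

    def __post_init__(self) -> None:
        if self.curvature < 0:
            raise ValueError("curvature must be nonnegative")
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))
        object.__setattr__(self, "subgrad", np.asarray(self.subgrad, dtype=float))

    def membership_value(self, x: np.ndarray) -> float:
        """<= 0 iff ``x`` belongs to the relaxed set."""
        d = self.anchor - np.asarray(x, dtype=float)
        return self.fval - float(self.subgrad @ d) + 0.5 * self.curvature * float(d @ d)

    def is_whole_space(self) -> bool:
        return (
            self.fval <= 0
            and not np.any(self.subgrad)
            and self.curvature == 0
        )


@dataclass
class SFPInstance:
    """A split feasibility problem: find ``w`` in C with ``A w`` in Q."""

    A: np.ndarray
    Cset: ConvexConstraint
    Qset: ConvexConstraint
    known_solution: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.size == 0:
            raise ValueError("A must be a nonempty 2-d matrix")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A must have finite entries")
        if self.known_solution is not None:
            w = np.asarray(self.known_solution, dtype=float)
            if self.Cset.value(w) > 1e-10 or self.Qset.value(self.A @ w) > 1e-10:
                raise ValueError("known_solution is not feasible for this instance")
            self.known_solution = w

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


def operator_norm_sq(A: np.ndarray) -> float:
    """Largest eigenvalue of ``A^T A``, i.e. the squared operator norm.

    This is the quantity appearing in every step-size bound of the CQ
    family (step sizes must stay below ``2 / ||A||^2``).  Computed by an
    exact symmetric eigensolver; the matrices involved are desk-scale.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("A must be nonempty")
    if not np.all(np.isfinite(A)):
        raise ValueError("A must have finite entries")
    if A.ndim != 2:
        raise ValueError("A must be 2-dimensional")
    # eigvalsh on the smaller Gram matrix; clamp tiny negative round-off
    G = A.T @ A if A.shape[0] >= A.shape[1] else A @ A.T
    return max(float(np.linalg.eigvalsh(G)[-1]), 0.0)


def project_halfspace(x: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Euclidean projection onto ``{w : <a, w> <= b}``."""
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    nrm2 = float(a @ a)
    if nrm2 == 0.0:
        if b >= 0:
            return x.copy()
        raise EmptySetError("half-space with zero normal and negative offset is empty")
    viol = float(a @ x) - b
    if viol <= 0:
        return x.copy()
    return x - (viol / nrm2) * a


def project_ball(x: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto the closed ball ``{w : ||w - center|| <= radius}``."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    d = x - center
    dist = float(np.linalg.norm(d))
    if dist <= radius:
        return x.copy()
    return center + (radius / dist) * d


def project_l1_ball(x: np.ndarray, gamma: float) -> np.ndarray:
    """Euclidean projection onto ``{w : ||w||_1 <= gamma}`` by sort-and-threshold.

    Standard simplex-projection reduction: project ``|x|`` onto the simplex
    of radius gamma, then restore signs.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    if ax.sum() <= gamma:
        return x.copy()
    u = np.sort(ax)[::-1]
    cum = np.cumsum(u) - gamma
    k = np.arange(1, x.size + 1)
    rho = np.nonzero(u > cum / k)[0][-1]
    theta = cum[rho] / (rho + 1.0)
    return np.sign(x) * np.maximum(ax - theta, 0.0)


def build_relaxed_set(
    constraint: ConvexConstraint, anchor: np.ndarray, curvature: float = 0.0
) -> RelaxedSet:
    """Evaluate the constraint's value and subgradient at ``anchor``.

    The resulting :class:`RelaxedSet` is the half-space (or, for positive
    curvature, ball) relaxation used by one solver iteration.
    """
    anchor = np.asarray(anchor, dtype=float)
    if not np.all(np.isfinite(anchor)):
        raise ValueError("anchor must be finite")
    fval = constraint.value(anchor)
    g = constraint.subgrad(anchor)
    if not np.isfinite(fval) or not np.all(np.isfinite(g)):
        raise FloatingPointError("constraint oracle returned non-finite output")
    return RelaxedSet(anchor=anchor, fval=fval, subgrad=g, curvature=curvature)


def project_relaxed(x: np.ndarray, S: RelaxedSet) -> np.ndarray:
    """Project onto a relaxed set.

    Zero curvature: the membership inequality
    ``fval <= <g, anchor - w>`` rewrites as ``<g, w> <= <g, anchor> - fval``,
    a half-space with normal ``g``.  Positive curvature: completing the
    square turns the set into the ball with center ``anchor - g/curvature``
    and squared radius ``||g||^2/curvature^2 - 2*fval/curvature``.
    """
    x = np.asarray(x, dtype=float)
    g = S.subgrad
    if S.curvature == 0.0:
        b = float(g @ S.anchor) - S.fval
        if not np.any(g) and S.fval > 0:
            raise EmptySetError("relaxed half-space with zero subgradient and positive value")
        return project_halfspace(x, g, b)
    r2 = float(g @ g) / S.curvature**2 - 2.0 * S.fval / S.curvature
    if r2 < 0:
        raise EmptySetError("relaxed ball has negative squared radius (curvature too large)")
    center = S.anchor - g / S.curvature
    return project_ball(x, center, np.sqrt(r2))


# ---------------------------------------------------------------------------
# Standard constraint constructors


def l1_ball_constraint(gamma: float) -> ConvexConstraint:
    """``c(w) = ||w||_1 - gamma``.

    Subgradient is the sign vector, with 0 taken at zero coordinates (a
    valid subdifferential element that keeps the relaxation as large as
    possible and the oracle deterministic).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return ConvexConstraint(
        value_oracle=lambda w: float(np.abs(w).sum()) - gamma,
        subgrad_oracle=np.sign,
        label="l1_ball",
        projector=lambda w: project_l1_ball(w, gamma),
    )


def l2_ball_constraint(gamma: float) -> ConvexConstraint:
    """``c(w) = ||w||_2^2 - gamma`` — the ball of radius ``sqrt(gamma)``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    radius = float(np.sqrt(gamma))

    def proj(w: np.ndarray) -> np.ndarray:
        return project_ball(w, np.zeros_like(w), radius)

    return ConvexConstraint(
        value_oracle=lambda w: float(w @ w) - gamma,
        subgrad_oracle=lambda w: 2.0 * w,
        label="l2_ball",
        projector=proj,
    )


def halfspace_constraint(a: np.ndarray, b: float) -> ConvexConstraint:
    """``c(w) = <a, w> - b``."""
    a = np.asarray(a, dtype=float)
    return ConvexConstraint(
        value_oracle=lambda w: float(a @ w) - b,
        subgrad_oracle=lambda w: a.copy(),
        label="halfspace",
        projector=lambda w: project_halfspace(w, a, b),
    )


def singleton_constraint(point: np.ndarray) -> ConvexConstraint:
    """``q(v) = 0.5 * ||v - point||^2`` — the singleton ``{point}``.

    This is the target-set description used when a linear system
    ``A w = point`` is posed as a split feasibility problem.
    """
    point = np.asarray(point, dtype=float)
    return ConvexConstraint(
        value_oracle=lambda v: 0.5 * float((v - point) @ (v - point)),
        subgrad_oracle=lambda v: v - point,
        label="singleton",
        projector=lambda v: point.copy(),
    )


def ball_set_constraint(center: np.ndarray, radius: float) -> ConvexConstraint:
    """``q(v) = ||v - center||^2 - radius^2`` — an off-center ball."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    center = np.asarray(center, dtype=float)
    return ConvexConstraint(
        value_oracle=lambda v: float((v - center) @ (v - center)) - radius**2,
        subgrad_oracle=lambda v: 2.0 * (v - center),
        label="ball",
        projector=lambda v: project_ball(v, center, radius),
    )


def box_constraint(lo: np.ndarray, hi: np.ndarray) -> ConvexConstraint:
    """``c(w) = max_i max(lo_i - w_i, w_i - hi_i)`` — an axis-aligned box."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo > hi):
        raise ValueError("box lower bounds exceed upper bounds")

    def value(w: np.ndarray) -> float:
        return float(np.maximum(lo - w, w - hi).max())

    def subgrad(w: np.ndarray) -> np.ndarray:
        viol = np.maximum(lo - w, w - hi)
        g = np.zeros_like(w)
        if viol.max() > 0:  # inside the box the value is <= 0; 0 is a subgradient
            i = int(np.argmax(viol))
            g[i] = -1.0 if lo[i] - w[i] >= w[i] - hi[i] else 1.0
        return g

    return ConvexConstraint(
        value_oracle=value,
        subgrad_oracle=subgrad,
        label="box",
        projector=lambda w: np.clip(w, lo, hi),
    )


_CONSTRAINT_FACTORIES = {
    "l1_ball": lambda p: l1_ball_constraint(p["gamma"]),
    "l2_ball": lambda p: l2_ball_constraint(p["gamma"]),
    "halfspace": lambda p: halfspace_constraint(p["a"], p["b"]),
    "singleton": lambda p: singleton_constraint(p["point"]),
    "ball": lambda p: ball_set_constraint(p["center"], p["radius"]),
    "box": lambda p: box_constraint(p["lo"], p["hi"]),
}


def make_constraint(kind: str, **params) -> ConvexConstraint:
    """Build one of the named standard constraints from keyword parameters."""
    try:
        factory = _CONSTRAINT_FACTORIES[kind]
    except KeyError:
        raise ValueError(
            f"unknown constraint kind {kind!r}; known: {sorted(_CONSTRAINT_FACTORIES)}"
        ) from None
    return factory(params)
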