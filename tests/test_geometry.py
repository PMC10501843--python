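"""Projections, relaxed sets, and the operator-norm bound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from relaxedcq.geometry import (
    EmptySetError,
    RelaxedSet,
    SFPInstance,
    build_relaxed_set,
    l1_ball_constraint,
    l2_ball_constraint,
    make_constraint,
    operator_norm_sq,
    project_ball,
    project_halfspace,
    project_l1_ball,
    project_relaxed,
    singleton_constraint,
)

from _oracles import (
    qp_project_ball,
    qp_project_halfspace,
    qp_project_l1_ball,
    qp_project_relaxed,
)

finite_vec = arrays(
    float, st.integers(2, 8),
    elements=st.floats(-10, 10, allow_nan=False, allow_infinity=False),
)


class TestOperatorNorm:
    def test_identity_and_diagonal(self):
        assert operator_norm_sq(np.eye(4)) == pytest.approx(1.0)
        assert operator_norm_sq(np.diag([3.0, 4.0])) == pytest.approx(16.0)

    def test_matches_svd(self, rng):
        A = rng.standard_normal((8, 5))
        smax = np.linalg.svd(A, compute_uv=False)[0]
        assert operator_norm_sq(A) == pytest.approx(smax**2, rel=1e-10)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            operator_norm_sq(np.array([[1.0, np.inf]]))
        with pytest.raises(ValueError):
            operator_norm_sq(np.empty((0, 0)))


class TestClosedFormProjections:
    @pytest.mark.parametrize(
        "x, a, b, expected",
        [
            ((-1, 2), (1, 0), 0.0, (-1, 2)),   # already feasible
            ((2, 3), (1, 0), 0.0, (0, 3)),     # axis-aligned drop
        ],
    )
    def test_halfspace_examples(self, x, a, b, expected):
        np.testing.assert_allclose(
            project_halfspace(np.array(x, float), np.array(a, float), b),
            expected, atol=1e-12,
        )

    def test_halfspace_degenerate_normal(self):
        x = np.array([1.0, 2.0])
        np.testing.assert_array_equal(project_halfspace(x, np.zeros(2), 0.0), x)
        with pytest.raises(EmptySetError):
            project_halfspace(x, np.zeros(2), -1.0)

    @pytest.mark.parametrize(
        "x, expected",
        [((0.3, 0.4), (0.3, 0.4)), ((3, 4), (0.6, 0.8))],
    )
    def test_unit_ball_examples(self, x, expected):
        out = project_ball(np.array(x, float), np.zeros(2), 1.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_ball_rejects_negative_radius(self):
        with pytest.raises(ValueError):
            project_ball(np.ones(2), np.zeros(2), -0.5)

    @pytest.mark.parametrize(
        "x, expected",
        [((0.5, 0.2), (0.5, 0.2)), ((2, 0), (1, 0))],
    )
    def test_l1_ball_examples(self, x, expected):
        out = project_l1_ball(np.array(x, float), 1.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert np.abs(out).sum() <= 1.0 + 1e-10

    def test_l1_ball_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            project_l1_ball(np.ones(3), 0.0)


class TestOracleEquivalence:
    """Each closed form matches the generic convex-programming minimizer."""

    def test_halfspace(self, rng):
        for _ in range(30):
            d = rng.integers(2, 6)
            x, a = rng.normal(size=d), rng.normal(size=d)
            b = rng.normal()
            np.testing.assert_allclose(
                project_halfspace(x, a, b), qp_project_halfspace(x, a, b), atol=1e-6
            )

    def test_ball(self, rng):
        for _ in range(30):
            d = rng.integers(2, 7)
            x, c = 3 * rng.normal(size=d), rng.normal(size=d)
            r = rng.uniform(0.1, 2.0)
            np.testing.assert_allclose(
                project_ball(x, c, r), qp_project_ball(x, c, r), atol=1e-6
            )

    def test_l1_ball(self, rng):
        for _ in range(30):
            d = rng.integers(2, 11)
            x = 3 * rng.normal(size=d)
            gamma = rng.uniform(0.5, 3.0)
            np.testing.assert_allclose(
                project_l1_ball(x, gamma), qp_project_l1_ball(x, gamma), atol=1e-6
            )

    def test_relaxed_sets(self, rng):
        for kappa in (0.0, 0.7, 2.0):
            for _ in range(15):
                d = rng.integers(2, 6)
                anchor = rng.normal(size=d)
                g = rng.normal(size=d)
                # keep the set nonempty: for kappa > 0 require r^2 >= 0
                fval = rng.uniform(-1, 1)
                if kappa > 0:
                    fval = min(fval, 0.4 * (g @ g) / kappa)
                S = RelaxedSet(anchor=anchor, fval=fval, subgrad=g, curvature=kappa)
                x = 2 * rng.normal(size=d)
                np.testing.assert_allclose(
                    project_relaxed(x, S), qp_project_relaxed(x, S), atol=1e-6
                )


class TestRelaxedSets:
    def test_spec_halfspace_case(self):
        S = RelaxedSet(anchor=np.zeros(2), fval=1.0, subgrad=np.array([1.0, 0.0]))
        np.testing.assert_allclose(project_relaxed(np.zeros(2), S), [-1.0, 0.0], atol=1e-12)

    def test_spec_ball_case(self):
        S = RelaxedSet(
            anchor=np.zeros(2), fval=0.0, subgrad=np.array([2.0, 0.0]), curvature=2.0
        )
        # completing the square: center (-1, 0), radius 1
        np.testing.assert_allclose(
            project_relaxed(np.array([1.0, 0.0]), S), [0.0, 0.0], atol=1e-12
        )

    def test_whole_space_and_empty(self):
        whole = RelaxedSet(anchor=np.zeros(2), fval=-1.0, subgrad=np.zeros(2))
        assert whole.is_whole_space()
        x = np.array([3.0, -2.0])
        np.testing.assert_array_equal(project_relaxed(x, whole), x)
        empty = RelaxedSet(anchor=np.zeros(2), fval=1.0, subgrad=np.zeros(2))
        with pytest.raises(EmptySetError):
            project_relaxed(x, empty)
        too_curved = RelaxedSet(
            anchor=np.zeros(2), fval=1.0, subgrad=np.array([0.1, 0.0]), curvature=5.0
        )
        with pytest.raises(EmptySetError):
            project_relaxed(x, too_curved)

    def test_build_relaxed_set_examples(self):
        c2 = l2_ball_constraint(17.0)
        S = build_relaxed_set(c2, np.zeros(3))
        assert S.fval == pytest.approx(-17.0)
        np.testing.assert_array_equal(S.subgrad, np.zeros(3))
        assert S.is_whole_space()

        c1 = l1_ball_constraint(7.0)
        S1 = build_relaxed_set(c1, np.array([3.0, -1.0]))
        assert S1.fval == pytest.approx(-3.0)
        np.testing.assert_array_equal(S1.subgrad, [1.0, -1.0])

    @pytest.mark.parametrize("kind, gamma", [("l1_ball", 7.0), ("l2_ball", 17.0)])
    def test_true_set_nested_in_relaxation(self, rng, kind, gamma):
        """Every feasible point of C lies in any relaxation built from c."""
        cons = make_constraint(kind, gamma=gamma)
        for _ in range(100):
            d = rng.integers(2, 8)
            anchor = 4 * rng.normal(size=d)
            S = build_relaxed_set(cons, anchor)
            w = rng.normal(size=d)
            # scale into the feasible set
            w = w * rng.uniform(0, 1) * (
                gamma / np.abs(w).sum() if kind == "l1_ball"
                else np.sqrt(gamma) / np.linalg.norm(w)
            )
            assert cons.value(w) <= 1e-10
            assert S.membership_value(w) <= 1e-9

    def test_subgradients_match_finite_differences(self, rng):
        """Differentiable constraint oracles agree with numerical gradients."""
        from _oracles import finite_diff_grad

        l2 = l2_ball_constraint(4.0)
        sing = singleton_constraint(np.array([1.0, -2.0, 0.5]))
        for cons in (l2, sing):
            x = rng.normal(size=3)
            num = finite_diff_grad(cons.value, x)
            np.testing.assert_allclose(cons.subgrad(x), num, rtol=1e-5, atol=1e-7)


class TestProjectionProperties:
    PROJECTIONS = [
        lambda v: project_halfspace(v, np.array([1.0, -2.0, 0.5]), 0.3),
        lambda v: project_ball(v, np.array([0.5, 0.0, -1.0]), 1.2),
        lambda v: project_l1_ball(v, 1.5),
        lambda v: project_relaxed(
            v,
            RelaxedSet(
                anchor=np.array([0.2, -0.1, 0.4]),
                fval=0.3,
                subgrad=np.array([1.0, 0.5, -0.2]),
                curvature=0.8,
            ),
        ),
    ]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        x=arrays(float, 3, elements=st.floats(-5, 5, allow_nan=False)),
        y=arrays(float, 3, elements=st.floats(-5, 5, allow_nan=False)),
    )
    def test_firmly_nonexpansive_and_idempotent(self, x, y):
        for P in self.PROJECTIONS:
            px, py = P(x), P(y)
            lhs = float((px - py) @ (px - py))
            rhs = float((px - py) @ (x - y))
            assert lhs <= rhs + 1e-10
            np.testing.assert_allclose(P(px), px, atol=1e-12)

    def test_feasibility_of_projection_output(self, rng):
        a, b = rng.normal(size=4), rng.normal()
        for _ in range(50):
            x = 5 * rng.normal(size=4)
            assert a @ project_halfspace(x, a, b) <= b + 1e-12


class TestSFPInstance:
    def test_rejects_infeasible_known_solution(self):
        A = np.eye(2)
        C = l2_ball_constraint(1.0)
        with pytest.raises(ValueError):
            SFPInstance(A=A, Cset=C, Qset=C, known_solution=np.array([5.0, 0.0]))

    def test_make_constraint_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown constraint"):
            make_constraint("moebius_strip")
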