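"""Generators, steady states, propagation and the delayed joint."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from regdiss.circuits import (
    CircuitParams,
    Generator4,
    ReducibleGeneratorWarning,
    SymDist,
    build_generator,
    delayed_joint,
    mu_of,
    propagate,
    relaxation_rate,
    steady_state,
)
from regdiss.synthetic import random_params


def no_feedback_pss(u, s, r=1.0):
    # printed stationary distribution of the no-feedback model
    d = 2 * s + 4 * u + 2 * r
    return np.array([u + r, s + u, s + u, u + r]) / d


class TestBuildGenerator:
    def test_uniform_rates_give_uniform_steady_state(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=1, r=1))
        assert np.allclose(steady_state(G).p, 0.25, atol=1e-12)

    def test_feedback_reduces_to_no_feedback_entrywise(self, rng):
        for _ in range(20):
            u, s = np.exp(rng.uniform(-3, 3, 2))
            Gf = build_generator(CircuitParams.feedback(alpha=u, y=u, s=s))
            Gn = build_generator(CircuitParams.no_feedback(u=u, s=s))
            assert np.array_equal(Gf.w, Gn.w)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            CircuitParams.no_feedback(u=-0.5, s=1)
        with pytest.raises(ValueError):
            CircuitParams.no_feedback(u=1, s=1, r=0)

    def test_columns_sum_to_zero_and_propagation_preserves_simplex(self, rng):
        for _ in range(1000):
            kind = "no_feedback" if rng.random() < 0.5 else "feedback"
            G = build_generator(random_params(kind, rng))
            assert np.allclose(G.Q.sum(axis=0), 0.0, atol=1e-9)
            p0 = SymDist(rng.uniform(-1, 1))
            t = rng.uniform(0, 3) / relaxation_rate(G)
            pt = propagate(G, p0, t)
            assert np.all(pt >= -1e-12)
            assert abs(pt.sum() - 1.0) < 1e-9


class TestSteadyState:
    def test_matches_printed_formula(self, rng):
        for _ in range(200):
            u, s = np.exp(rng.uniform(-3, 3, 2))
            G = build_generator(CircuitParams.no_feedback(u=u, s=s))
            assert np.allclose(steady_state(G).p, no_feedback_pss(u, s), atol=1e-12)

    def test_printed_value_u1_s3(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=3))
        assert np.allclose(steady_state(G).p, [1 / 6, 1 / 3, 1 / 3, 1 / 6], atol=1e-12)

    def test_feedback_against_long_time_propagation(self, rng):
        # independent oracle: matrix-exponential relaxation from uniform
        for _ in range(25):
            params = random_params("feedback", rng, log_range=(0.1, 10))
            G = build_generator(params)
            lam = relaxation_rate(G)
            p_inf = expm(G.Q * (60.0 / lam)) @ np.full(4, 0.25)
            assert np.allclose(steady_state(G).p, p_inf, atol=1e-9)

    def test_feedback_example(self):
        G = build_generator(CircuitParams.feedback(alpha=2, y=1, s=0.5))
        p = steady_state(G).p
        assert np.allclose(G.Q @ p, 0, atol=1e-12)

    def test_reducible_generator_warns(self):
        G = build_generator(CircuitParams.no_feedback(u=0.0, s=1.0))
        with pytest.warns(ReducibleGeneratorWarning):
            steady_state(G)


class TestRelaxationRate:
    @pytest.mark.parametrize(
        "u,s,expected", [(0.4, 0.5, 0.8), (1.0, 1.0, 2.0), (3.0, 0.2, 1.2)]
    )
    def test_no_feedback_examples(self, u, s, expected):
        G = build_generator(CircuitParams.no_feedback(u=u, s=s))
        assert relaxation_rate(G) == pytest.approx(expected, abs=1e-10)

    def test_no_feedback_closed_form(self, rng):
        for _ in range(200):
            u, s = np.exp(rng.uniform(-3, 3, 2))
            G = build_generator(CircuitParams.no_feedback(u=u, s=s))
            assert relaxation_rate(G) == pytest.approx(min(1 + s, 2 * u), rel=1e-10)

    def test_feedback_closed_form_when_real(self, rng):
        # lambda = (A - rho)/2, A = 1+s+y+alpha, rho = sqrt(A^2 - 8(sy+alpha))
        checked = 0
        while checked < 100:
            a, y, s = np.exp(rng.uniform(-2, 2, 3))
            A = 1 + s + y + a
            disc = A * A - 8 * (s * y + a)
            if disc <= 1e-6:
                continue
            G = build_generator(CircuitParams.feedback(alpha=a, y=y, s=s))
            lam = (A - np.sqrt(disc)) / 2
            assert relaxation_rate(G) == pytest.approx(lam, rel=1e-8)
            checked += 1


class TestPropagate:
    def test_time_zero_is_identity(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=2))
        p0 = SymDist(0.3)
        assert np.allclose(propagate(G, p0, 0.0), p0.p, atol=1e-14)

    def test_long_time_reaches_steady_state(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=2))
        pt = propagate(G, SymDist(1.0), 50.0)
        assert np.allclose(pt, steady_state(G).p, atol=1e-10)

    def test_against_ode_solver(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=2))
        p0 = SymDist(1.0).p
        sol = solve_ivp(lambda t, p: G.Q @ p, (0, 0.3), p0, rtol=1e-12, atol=1e-14)
        assert np.allclose(propagate(G, SymDist(1.0), 0.3), sol.y[:, -1], atol=1e-9)

    def test_negative_time_rejected(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=2))
        with pytest.raises(ValueError):
            propagate(G, SymDist(0.0), -0.1)


def brute_force_delayed_joint(G, p0_vec, t):
    """Direct sum over all 16 (z0,x0) -> (zt,xt) conditional paths."""
    T = expm(G.Q * t)
    pxz = np.zeros((2, 2))
    for z0 in range(2):
        for x0 in range(2):
            j = 2 * z0 + x0
            for zt in range(2):
                for xt in range(2):
                    i = 2 * zt + xt
                    pxz[z0, xt] += T[i, j] * p0_vec[j]
    return pxz


class TestDelayedJoint:
    def test_time_zero_returns_mu0(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=2))
        for mu0 in (-0.4, 0.0, 0.7, 1.0):
            dj = delayed_joint(G, SymDist(mu0), 0.0)
            assert mu_of(dj) == pytest.approx(mu0, abs=1e-12)

    def test_matches_brute_force_path_sum(self, rng):
        for _ in range(25):
            kind = "no_feedback" if rng.random() < 0.5 else "feedback"
            G = build_generator(random_params(kind, rng, log_range=(0.05, 20)))
            mu0 = rng.uniform(-1, 1)
            t = rng.uniform(0, 2) / relaxation_rate(G)
            dj = delayed_joint(G, SymDist(mu0), t)
            assert np.allclose(dj.pxz, brute_force_delayed_joint(G, SymDist(mu0).p, t),
                               atol=1e-12)

    def test_long_time_decorrelates(self):
        G = build_generator(CircuitParams.no_feedback(u=1, s=2))
        dj = delayed_joint(G, SymDist(1.0), 80.0)
        assert mu_of(dj) == pytest.approx(0.0, abs=1e-10)

    def test_symmetry_closure(self, rng):
        # symmetric p0 stays in the symmetric class for all times
        for _ in range(100):
            kind = "no_feedback" if rng.random() < 0.5 else "feedback"
            G = build_generator(random_params(kind, rng))
            t = rng.uniform(0, 5) / relaxation_rate(G)
            dj = delayed_joint(G, SymDist(rng.uniform(-1, 1)), t)
            mu_of(dj, tol=1e-7)  # raises if the class is left


class TestMuOf:
    def test_uniform_gives_zero(self):
        from regdiss.circuits import DelayedJoint

        assert mu_of(DelayedJoint(np.full((2, 2), 0.25), 0.0)) == 0.0

    def test_aligned_and_anti_aligned_point_masses(self):
        from regdiss.circuits import DelayedJoint

        aligned = DelayedJoint(np.array([[0.5, 0.0], [0.0, 0.5]]), 0.0)
        anti = DelayedJoint(np.array([[0.0, 0.5], [0.5, 0.0]]), 0.0)
        assert mu_of(aligned) == 1.0
        assert mu_of(anti) == -1.0

    def test_asymmetric_joint_rejected_with_named_symmetry(self):
        from regdiss.circuits import DelayedJoint

        bad = DelayedJoint(np.array([[0.4, 0.1], [0.1, 0.4]]) +
                           np.array([[0.05, 0], [0, -0.05]]), 0.0)
        with pytest.raises(ValueError, match="symmetry"):
            mu_of(bad)


def test_no_feedback_mu_t_against_symbolic_eigendecomposition():
    """Cross-check the numerical propagator against an exact symbolic
    eigen-decomposition of the rational-rate generator."""
    import sympy as sp

    u, s, r = sp.Integer(1), sp.Integer(2), sp.Integer(1)
    Q = sp.Matrix(
        [
            [-(s + u), r, u, 0],
            [s, -(r + u), 0, u],
            [u, 0, -(r + u), s],
            [0, u, r, -(s + u)],
        ]
    )
    t = sp.Rational(3, 10)
    T = (Q * t).exp()
    mu0 = sp.Integer(1)
    p0 = sp.Matrix([(1 + mu0) / 4, (1 - mu0) / 4, (1 - mu0) / 4, (1 + mu0) / 4])
    pxz = sp.zeros(2, 2)
    for z0 in range(2):
        for x0 in range(2):
            j = 2 * z0 + x0
            for i in range(4):
                pxz[z0, i % 2] += T[i, j] * p0[j]
    mu_sym = float(sp.nsimplify(2 * (pxz[0, 0] + pxz[1, 1]) - 1).evalf(30))

    G = build_generator(CircuitParams.no_feedback(u=1, s=2))
    dj = delayed_joint(G, SymDist(1.0), 0.3)
    assert mu_of(dj) == pytest.approx(mu_sym, abs=1e-12)
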