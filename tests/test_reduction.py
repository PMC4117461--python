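"""Eigenframe transform, fast-mode elimination, reduced equation, bifurcation."""

import numpy as np
import pytest

import cofluct as cf
from cofluct.reduction import (_eliminate_from_modal, _modal_field,
                               N_MONOMIALS, ReductionError)


class TestMatrixAtCritical:
    def test_delegates_to_linearization(self, fig2):
        Lc = cf.matrix_at_critical(fig2, p_c=0.8)
        q = fig2.with_p(0.8)
        L = cf.linearize(q, cf.steady_state(q))
        assert Lc == L

    def test_near_singular_at_critical_supply(self, fig2):
        Lc = cf.matrix_at_critical(fig2, p_c=0.8)
        assert abs(Lc.det) < 0.01
        assert Lc.trace < 0

    def test_invalid_pc_rejected(self, fig2):
        with pytest.raises(ValueError):
            cf.matrix_at_critical(fig2, p_c=0.1)


class TestEigenTransform:
    def test_diagonal_input(self):
        frame = cf.eigen_transform(cf.LinearOperator(-1.0, 0.0, 0.0, 0.0))
        assert frame.lam_v == 0.0 and frame.lam_u == -1.0
        # v aligned with the zero-eigenvalue direction (second axis)
        assert np.allclose(frame.basis, np.eye(2))

    def test_similarity_identity(self, fig2, frame):
        Lc = cf.matrix_at_critical(fig2).as_array()
        D = frame.basis_inv @ Lc @ frame.basis
        assert abs(D[0, 1]) < 1e-10 and abs(D[1, 0]) < 1e-10
        assert D[0, 0] == pytest.approx(frame.lam_u, abs=1e-10)
        assert D[1, 1] == pytest.approx(frame.lam_v, abs=1e-10)

    def test_eigenvector_equations(self, fig2, frame):
        Lc = cf.matrix_at_critical(fig2).as_array()
        for col, lam in ((0, frame.lam_u), (1, frame.lam_v)):
            v = frame.basis[:, col]
            assert np.allclose(Lc @ v, lam * v, atol=1e-10)

    def test_slow_mode_near_zero_fast_negative(self, frame):
        assert abs(frame.lam_v) < 0.01
        assert frame.lam_u < -0.4

    def test_round_trip_transform(self, frame):
        xz = np.array([1e-4, -2e-4])
        assert np.allclose(frame.from_modal(frame.to_modal(xz)), xz,
                           atol=1e-12)

    def test_complex_eigenvalues_rejected(self):
        with pytest.raises(ReductionError, match="complex"):
            cf.eigen_transform(cf.LinearOperator(0.0, -1.0, 1.0, 0.0))

    def test_defective_matrix_rejected(self):
        with pytest.raises(ReductionError, match="defective"):
            cf.eigen_transform(cf.LinearOperator(1.0, 1.0, 0.0, 1.0))


class TestEliminateU:
    def test_decoupled_toy_field_gives_zero_coefficients(self):
        # du/dt = -u + u^2, dv/dt = v^2: no cross terms slave u to v
        gu = {(1, 0, 0): -1.0, (2, 0, 0): 1.0}
        a = _eliminate_from_modal(gu, order=(2, 1))
        assert all(v == 0.0 for v in a.values())

    def test_no_fast_linear_term_is_singular(self):
        with pytest.raises(ReductionError, match="singular"):
            _eliminate_from_modal({(0, 2, 0): 1.0}, order=(2, 1))

    def test_matched_monomials_vanish_after_substitution(self, fig2, frame):
        gu, _ = _modal_field(fig2, frame)
        a = cf.eliminate_u(fig2, frame, order=(2, 1))
        scale = max(abs(v) for v in gu.values())
        # rebuild the residual polynomial of the fast-mode equation
        from cofluct.reduction import _compose, _WORK_DV, _WORK_DE
        H = np.zeros((_WORK_DV + 1, _WORK_DE + 1))
        for (i, j), val in a.items():
            H[i, j] = val
        R = _compose(gu, H)
        for (i, j) in a:
            assert abs(R[i, j]) < 1e-9 * scale

    def test_residual_is_higher_order_on_sample_box(self, fig2, frame):
        """|G_u(h(v, eps), v, eps)| <= C (|v| + eps)^3 on the sample box."""
        gu, _ = _modal_field(fig2, frame)
        a = cf.eliminate_u(fig2, frame, order=(2, 1))

        def G_u(u, v, eps):
            return sum(c * u**k * v**l * eps**m for (k, l, m), c in gu.items())

        def h(v, eps):
            return sum(val * v**i * eps**j for (i, j), val in a.items())

        # calibrate C at the box edge, then check decay toward the origin
        for s in (1.0, 0.5, 0.25, 0.125):
            v, eps = s * 1e-3, s * 1e-3
            res = abs(G_u(h(v, eps), v, eps))
            assert res <= 1e9 * (abs(v) + eps) ** 3

    def test_deterministic_reproducibility(self, fig2, frame):
        a1 = cf.eliminate_u(fig2, frame)
        a2 = cf.eliminate_u(fig2, frame)
        assert a1 == a2

    def test_higher_order_extends_lower(self, fig2, frame):
        """The (3,1) ansatz agrees with (2,1) on shared monomials."""
        a2 = cf.eliminate_u(fig2, frame, order=(2, 1))
        a3 = cf.eliminate_u(fig2, frame, order=(3, 1))
        for mon, val in a2.items():
            assert a3[mon] == pytest.approx(val, rel=1e-12, abs=1e-12)


class TestSymbolicOracle:
    """Cross-check the numeric elimination against an independent symbolic
    route: solve the fast-mode equation G_u(u, v, eps) = 0 exactly for u by
    the quadratic formula (the branch with u -> 0 at the origin) and read
    the slaving coefficients off its Taylor expansion."""

    def test_elimination_matches_quadratic_formula_expansion(self, fig2, frame):
        sp = pytest.importorskip("sympy")
        gu, _ = _modal_field(fig2, frame)
        u, v, eps = sp.symbols("u v eps")
        G = sum(sp.Float(c, 17) * u**k * v**l * eps**m
                for (k, l, m), c in gu.items())
        A = sp.expand(G).coeff(u, 2)
        B = sp.expand(G).coeff(u, 1)
        C = sp.expand(G).coeff(u, 0)
        h_exact = (-B - sp.sqrt(B**2 - 4 * A * C)) / (2 * A)
        # the +sqrt branch vanishes at v = eps = 0 for this sign of B
        if abs(complex(h_exact.subs({v: 0, eps: 0}))) > 1e-12:
            h_exact = (-B + sp.sqrt(B**2 - 4 * A * C)) / (2 * A)
        a_num = cf.eliminate_u(fig2, frame, order=(2, 1))
        # extract series coefficients by small-step finite differencing of
        # the exact branch is fragile; use sympy's series instead
        s = h_exact
        for var, n in ((v, 3), (eps, 2)):
            s = sp.series(s, var, 0, n).removeO()
        poly = sp.Poly(sp.expand(s), v, eps)
        for (i, j), want in a_num.items():
            got = float(poly.coeff_monomial(v**i * eps**j))
            assert got == pytest.approx(want, rel=1e-6, abs=1e-10)


class TestReducedEquation:
    def test_six_coefficients_produced(self, reduced):
        assert len(reduced.n) == 6
        assert len(N_MONOMIALS) == 6
        assert all(np.isfinite(reduced.n))

    def test_linear_in_v_coefficient_is_slow_eigenvalue(self, frame, reduced):
        # at eps = 0 the v-linear coefficient must equal lam_v
        assert reduced.n[0] == pytest.approx(frame.lam_v, rel=1e-9)

    def test_no_constant_term(self, reduced):
        assert all(i >= 1 for (i, j) in reduced.terms)

    def test_zero_elimination_reproduces_bare_slow_field(self, fig2, frame):
        _, gv = _modal_field(fig2, frame)
        m = cf.reduced_equation(fig2, frame, {})
        for (i, j), coeff in m.terms.items():
            assert coeff == pytest.approx(gv.get((0, i, j), 0.0), rel=1e-12)

    def test_reduced_field_matches_full_slow_component(self, fig2, frame, reduced):
        """f(v, eps) agrees with G_v evaluated along u = h(v, eps) to the
        truncation order."""
        _, gv = _modal_field(fig2, frame)
        a = reduced.elimination

        def G_v(u, v, eps):
            return sum(c * u**k * v**l * eps**m for (k, l, m), c in gv.items())

        def h(v, eps):
            return sum(val * v**i * eps**j for (i, j), val in a.items())

        for s in (1.0, 0.5, 0.25):
            v, eps = s * 1e-4, s * 1e-4
            full = G_v(h(v, eps), v, eps)
            red = sum(c * v**i * eps**j for (i, j), c in reduced.terms.items())
            # discrepancy is the truncated tail, fourth order in (|v| + eps)
            assert abs(red - full) <= 1e10 * (abs(v) + eps) ** 4


class TestEquilibria:
    def test_pitchfork_toy(self):
        m = cf.ReducedModel.from_coefficients({(1, 0): 1.0, (3, 0): -1.0})
        roots = cf.equilibria_of_v(m, 0.0)
        assert np.allclose(sorted(roots), [-1.0, 0.0, 1.0])

    def test_only_zero_root_toy(self):
        m = cf.ReducedModel.from_coefficients({(1, 0): -1.0, (3, 0): -1.0})
        roots = cf.equilibria_of_v(m, 0.0)
        assert np.allclose(roots, [0.0])

    def test_negative_eps_rejected(self, reduced):
        with pytest.raises(ValueError):
            cf.equilibria_of_v(reduced, -0.1)

    def test_reference_reduction_bistable_at_small_eps(self, reduced):
        assert cf.count_nonzero_roots(reduced, 1e-4) == 2

    def test_nonzero_roots_map_to_nonzero_xz_amplitudes(self, frame, reduced):
        roots = cf.equilibria_of_v(reduced, 1e-4)
        for v in roots[np.abs(roots) > 1e-12]:
            xz = frame.from_modal([0.0, v])
            assert np.linalg.norm(xz) > 0


class TestBifurcationThreshold:
    def test_toy_threshold_recovered_exactly(self):
        # dv/dt = (eps0 - eps) v - v^3: nonzero roots exist below eps0
        eps0 = 0.01
        m = cf.ReducedModel.from_coefficients(
            {(1, 0): eps0, (1, 1): -1.0, (3, 0): -1.0})
        bif = cf.bifurcation_threshold(m, eps_hi=0.25)
        assert bif.eps_star == pytest.approx(eps0, rel=2e-3)

    def test_root_count_changes_exactly_once(self, reduced):
        bif = cf.bifurcation_threshold(reduced, eps_hi=0.25)
        changes = np.sum(np.diff(bif.root_counts) != 0)
        assert changes == 1

    def test_identical_endpoint_counts_is_error(self):
        m = cf.ReducedModel.from_coefficients({(1, 0): 1.0, (3, 0): -1.0})
        with pytest.raises(ReductionError, match="does not change"):
            cf.bifurcation_threshold(m, eps_hi=0.25)

    def test_threshold_converged_in_tolerance(self, reduced):
        b1 = cf.bifurcation_threshold(reduced, rel_tol=1e-3)
        b2 = cf.bifurcation_threshold(reduced, rel_tol=1e-4)
        assert b1.eps_star == pytest.approx(b2.eps_star, rel=1e-2)
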