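"""Eigenvector-coordinate stability reduction at the critical supply level.

At p = p_c the linearization L_c of the fluctuation field has one eigenvalue
near zero (the slow, critical mode) and one clearly negative (the fast mode).
Working in the eigenbasis coordinates (u, v) — u fast, v slow — the fast mode
is eliminated adiabatically: u is slaved to a polynomial u = h(v, eps) in the
slow mode and the distance eps = p - p_c above criticality, determined by
requiring the fast-mode equation to vanish order by order in (v, eps).
Substituting h into the slow-mode equation yields a one-dimensional reduced
stability equation, a cubic in v whose six coefficients n_i (i = 1..6)
multiply the monomials v, v*eps, v^2, v^2*eps, v^3, v^3*eps.  The real roots
of the reduced fixed-point equation, and the eps at which their count
changes (eps_star), predict amplitude bi-stability of the fluctuation.

eps enters through the p-dependence of both the linear matrix and the steady
state: the full field is re-expanded about p_c to first order in eps
(complex-step differentiation, so the expansion is exact to machine
precision).  The elimination order is configurable; the default ansatz is
degree 2 in v and degree 1 in eps, the minimal order producing all six n_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (ModelParameters, SteadyState, LinearOperator,
                    _steady_state_values, field_coefficients, linearize,
                    steady_state)

__all__ = [
    "ReductionError",
    "EigenFrame",
    "ReducedModel",
    "BifurcationResult",
    "matrix_at_critical",
    "eigen_transform",
    "eliminate_u",
    "reduced_equation",
    "equilibria_of_v",
    "bifurcation_threshold",
]

#: Default distance above criticality at which the published simulation is
#: analyzed; the exact determinant root of the reference set is ~0.8042.
DEFAULT_PC = 0.8

#: Nonzero-root tolerance on |v|.
ROOT_TOL = 1e-12

# working truncation for internal polynomial algebra (degrees in v and eps)
_WORK_DV = 9
_WORK_DE = 4


class ReductionError(RuntimeError):
    """Raised when the eigenstructure or the elimination is unusable."""


# ---------------------------------------------------------------------------
# eigenframe


@dataclass(frozen=True)
class EigenFrame:
    """Eigenbasis of L_c and the (x, z) <-> (u, v) transforms.

    ``basis`` has the fast eigenvector as its first column and the slow
    (eigenvalue nearest zero) as its second; both are unit length with first
    nonzero component positive.  ``(x, z) = basis @ (u, v)``.
    """

    lam_u: float
    lam_v: float
    basis: np.ndarray
    basis_inv: np.ndarray

    def to_modal(self, xz) -> np.ndarray:
        return self.basis_inv @ np.asarray(xz, dtype=float)

    def from_modal(self, uv) -> np.ndarray:
        return self.basis @ np.asarray(uv, dtype=float)


def matrix_at_critical(params: ModelParameters,
                       p_c: float = DEFAULT_PC) -> LinearOperator:
    """Linearization at the critical supply level (delegates to the core)."""
    q = params.with_p(p_c).validate()
    return linearize(q, steady_state(q))


def eigen_transform(Lc: LinearOperator) -> EigenFrame:
    """Eigenbasis of L_c with the slow mode second.

    Requires distinct real eigenvalues; a complex or defective eigenstructure
    raises :class:`ReductionError` naming the eigenvalues.
    """
    A = Lc.as_array()
    w, V = np.linalg.eig(A)
    if np.any(np.abs(w.imag) > 1e-12 * max(1.0, float(np.abs(w).max()))):
        raise ReductionError(
            f"L_c has complex eigenvalues {w}; the eigenvector transform "
            "requires distinct real eigenvalues"
        )
    w = w.real
    V = V.real
    if abs(w[0] - w[1]) <= 1e-12 * max(1.0, float(np.abs(w).max())):
        raise ReductionError(f"L_c is (near-)defective: eigenvalues {w}")
    i_v = int(np.argmin(np.abs(w)))  # slow mode: eigenvalue nearest zero
    i_u = 1 - i_v
    P = np.column_stack([V[:, i_u], V[:, i_v]])
    for j in range(2):
        col = P[:, j] / np.linalg.norm(P[:, j])
        nz = np.nonzero(np.abs(col) > 1e-300)[0][0]
        if col[nz] < 0:
            col = -col
        P[:, j] = col
    return EigenFrame(lam_u=float(w[i_u]), lam_v=float(w[i_v]),
                      basis=P, basis_inv=np.linalg.inv(P))


# ---------------------------------------------------------------------------
# the modal field G(u, v, eps)


def _eps_expanded_coefficients(params: ModelParameters, p_c: float):
    """Field coefficients expanded about p_c to first order in eps.

    Returns ``(c0x, c0z, c1x, c1z)``: monomial dicts in (x, z) for the field
    at p_c and for its exact d/dp (complex-step differentiation; the steady
    state's p-dependence is included).
    """
    h = 1e-20
    X0, Z0 = _steady_state_values(params, p=p_c)
    c0x, c0z = field_coefficients(params, SteadyState(X0, Z0), p=p_c)
    Xc, Zc = _steady_state_values(params, p=p_c + 1j * h)
    cx_c, cz_c = field_coefficients(params, SteadyState(Xc, Zc), p=p_c + 1j * h)
    c1x = {k: v.imag / h for k, v in cx_c.items()}
    c1z = {k: v.imag / h for k, v in cz_c.items()}
    return c0x, c0z, c1x, c1z


def _modal_field(params: ModelParameters, frame: EigenFrame,
                 p_c: float = DEFAULT_PC):
    """Transformed field G = basis_inv @ F(basis @ (u, v); p_c + eps).

    Returns ``(gu, gv)``: dicts mapping ``(k, l, m)`` — the exponents of
    ``u**k * v**l * eps**m`` — to coefficients, with k + l <= 2, m <= 1.
    """
    c0x, c0z, c1x, c1z = _eps_expanded_coefficients(params, p_c)
    P = frame.basis
    Pinv = frame.basis_inv
    gu: dict = {}
    gv: dict = {}

    def accumulate(cdict, m, wx, wz):
        # wx, wz: weights of this field component in (gu, gv) resp.
        for (i, j), coeff in cdict.items():
            # expand (P00 u + P01 v)^i (P10 u + P11 v)^j
            for ki in range(i + 1):
                bi = _binom(i, ki) * P[0, 0] ** ki * P[0, 1] ** (i - ki)
                for kj in range(j + 1):
                    bj = _binom(j, kj) * P[1, 0] ** kj * P[1, 1] ** (j - kj)
                    k, l = ki + kj, (i - ki) + (j - kj)
                    w = coeff * bi * bj
                    gu[(k, l, m)] = gu.get((k, l, m), 0.0) + wx * w
                    gv[(k, l, m)] = gv.get((k, l, m), 0.0) + wz * w

    for m, (cx, cz) in enumerate([(c0x, c0z), (c1x, c1z)]):
        accumulate(cx, m, Pinv[0, 0], Pinv[1, 0])
        accumulate(cz, m, Pinv[0, 1], Pinv[1, 1])
    # drop numerically-zero entries for clarity
    gu = {k: v for k, v in gu.items() if v != 0.0}
    gv = {k: v for k, v in gv.items() if v != 0.0}
    return gu, gv


_BINOM = {(0, 0): 1, (1, 0): 1, (1, 1): 1, (2, 0): 1, (2, 1): 2, (2, 2): 1}


def _binom(n, k):
    return float(_BINOM[(n, k)])  # the field is quadratic; n <= 2


# ---------------------------------------------------------------------------
# polynomial algebra in (v, eps): coefficient arrays A[i, j] ~ v**i eps**j


def _pmul(A, B):
    out = np.zeros((_WORK_DV + 1, _WORK_DE + 1))
    ia, ja = np.nonzero(A)
    ib, jb = np.nonzero(B)
    for i1, j1 in zip(ia, ja):
        for i2, j2 in zip(ib, jb):
            i, j = i1 + i2, j1 + j2
            if i <= _WORK_DV and j <= _WORK_DE:
                out[i, j] += A[i1, j1] * B[i2, j2]
    return out


def _compose(g, H):
    """Coefficients of g(h(v, eps), v, eps) as a (v, eps) array."""
    kmax = max(k for k, _, _ in g)
    powers = [np.zeros((_WORK_DV + 1, _WORK_DE + 1))]
    powers[0][0, 0] = 1.0
    for _ in range(kmax):
        powers.append(_pmul(powers[-1], H))
    out = np.zeros((_WORK_DV + 1, _WORK_DE + 1))
    for (k, l, m), coeff in g.items():
        Hk = powers[k]
        ii, jj = np.nonzero(Hk)
        for i, j in zip(ii, jj):
            i2, j2 = i + l, j + m
            if i2 <= _WORK_DV and j2 <= _WORK_DE:
                out[i2, j2] += coeff * Hk[i, j]
    return out


# ---------------------------------------------------------------------------
# elimination of the fast mode


def _elimination_monomials(order):
    dv, de = order
    if dv < 1 or de < 0:
        raise ValueError(f"order must be (dv >= 1, de >= 0), got {order}")
    return [(i, j) for i in range(1, dv + 1) for j in range(de + 1)]


def _eliminate_from_modal(gu: dict, order=(2, 1)) -> dict:
    """Solve the fast-mode slaving condition for the ansatz coefficients.

    The ansatz is ``u = sum a_(i,j) v**i eps**j`` over 1 <= i <= dv,
    0 <= j <= de; the condition is that the coefficients of those same
    monomials in ``G_u(h(v, eps), v, eps)`` vanish.  Although G_u is
    quadratic in u, the matching system is triangular in graded monomial
    order — each a_(i,j) enters its own equation linearly with coefficient
    lam_u (the u-linear, eps-free entry of G_u) and is otherwise fed only by
    strictly lower-degree coefficients — so it is solved by exact forward
    substitution.
    """
    mons = sorted(_elimination_monomials(order), key=lambda m: (m[0] + m[1], m[0]))
    lam_u = gu.get((1, 0, 0), 0.0)
    if lam_u == 0.0:
        raise ReductionError(
            "singular matching system: the fast-mode equation has no "
            f"u-linear term, cannot solve for monomials {mons}"
        )
    a: dict = {}

    def residual_at(mon):
        H = np.zeros((_WORK_DV + 1, _WORK_DE + 1))
        for (i, j), val in a.items():
            H[i, j] = val
        return _compose(gu, H)[mon[0], mon[1]]

    for mon in mons:
        a[mon] = 0.0
        a[mon] = -residual_at(mon) / lam_u

    res_norm = float(max(abs(residual_at(m)) for m in mons))
    scale = max(1.0, float(np.max(np.abs(list(gu.values())))))
    if res_norm > 1e-8 * scale:
        raise ReductionError(
            "fast-mode matching left a residual for monomials "
            f"{mons}: {res_norm:.3g}"
        )
    return {mon: float(val) for mon, val in sorted(a.items())}


def eliminate_u(params: ModelParameters, frame: EigenFrame, order=(2, 1),
                p_c: float = DEFAULT_PC) -> dict:
    """Elimination coefficients a_(i,j) of u = h(v, eps) for the model."""
    gu, _ = _modal_field(params, frame, p_c)
    return _eliminate_from_modal(gu, order)


# ---------------------------------------------------------------------------
# the reduced slow-mode equation


#: Monomial order of the six reduced coefficients n_1..n_6.
N_MONOMIALS = ((1, 0), (1, 1), (2, 0), (2, 1), (3, 0), (3, 1))


@dataclass(frozen=True)
class ReducedModel:
    """One-dimensional reduced stability equation dv/dt = f(v, eps).

    ``terms`` holds the truncated bivariate polynomial (degree <= 3 in v,
    <= 2 in eps).  ``n`` are the six coefficients n_1..n_6 of the monomials
    v, v*eps, v^2, v^2*eps, v^3, v^3*eps — the part of the polynomial within
    the matched order of the elimination; root analysis uses these six.
    """

    terms: dict
    elimination: dict = field(default_factory=dict)
    order: tuple = (2, 1)
    p_c: float = DEFAULT_PC
    frame: EigenFrame | None = None

    @property
    def n(self) -> tuple:
        return tuple(self.terms.get(mon, 0.0) for mon in N_MONOMIALS)

    @classmethod
    def from_coefficients(cls, terms: dict, **kw) -> "ReducedModel":
        """Build directly from ``{(i, j): coefficient}`` (used for toys)."""
        return cls(terms={k: float(v) for k, v in terms.items()}, **kw)

    def cubic_coefficients(self, eps: float) -> tuple:
        """(c1, c2, c3) of f(v)/v = c1 + c2 v + c3 v^2 at a given eps,
        using the six matched-order coefficients."""
        n = dict(zip(N_MONOMIALS, self.n))
        c1 = n[(1, 0)] + n[(1, 1)] * eps
        c2 = n[(2, 0)] + n[(2, 1)] * eps
        c3 = n[(3, 0)] + n[(3, 1)] * eps
        return c1, c2, c3

    def evaluate(self, v: float, eps: float) -> float:
        """The full stored polynomial f(v, eps)."""
        return float(sum(coeff * v**i * eps**j
                         for (i, j), coeff in self.terms.items()))


def reduced_equation(params: ModelParameters, frame: EigenFrame,
                     a_coeffs: dict, order=(2, 1),
                     p_c: float = DEFAULT_PC) -> ReducedModel:
    """Substitute u = h(v, eps) into the slow-mode equation and truncate.

    Expands G_v(h(v, eps), v, eps), keeps degree <= 3 in v and <= 2 in eps,
    and reads off the coefficients.  The polynomial has no v-constant term
    (the quiescent state v = 0 persists for all eps); this is checked.
    """
    _, gv = _modal_field(params, frame, p_c)
    H = np.zeros((_WORK_DV + 1, _WORK_DE + 1))
    for (i, j), a in a_coeffs.items():
        H[i, j] = a
    F = _compose(gv, H)
    scale = max(1.0, float(np.max(np.abs(F))))
    if np.max(np.abs(F[0, :])) > 1e-10 * scale:
        raise ReductionError(
            f"reduced equation acquired a v-constant term {F[0, :]} "
            "(the quiescent state must persist)"
        )
    terms = {(i, j): float(F[i, j])
             for i in range(1, 4) for j in range(3) if F[i, j] != 0.0}
    return ReducedModel(terms=terms, elimination=dict(a_coeffs), order=order,
                        p_c=p_c, frame=frame)


def equilibria_of_v(model: ReducedModel, eps: float) -> np.ndarray:
    """All real roots of the reduced fixed-point equation at a given eps.

    Returns the sorted real roots of ``v (c1 + c2 v + c3 v^2) = 0``; v = 0 is
    always among them.  Double roots at a fold are reported once.
    """
    if eps < 0:
        raise ValueError(f"eps must be nonnegative, got {eps}")
    c1, c2, c3 = model.cubic_coefficients(eps)
    if c3 != 0.0:
        rr = np.roots([c3, c2, c1])
    elif c2 != 0.0:
        rr = np.array([-c1 / c2])
    else:
        rr = np.array([])
    scale = max(ROOT_TOL, float(np.max(np.abs(rr))) if rr.size else 0.0)
    real = [float(r.real) for r in rr if abs(r.imag) <= 1e-9 * scale]
    roots = [0.0]
    for r in sorted(real):
        if all(abs(r - q) > 1e-9 * max(1.0, abs(r)) for q in roots):
            roots.append(r)
    return np.array(sorted(roots))


def count_nonzero_roots(model: ReducedModel, eps: float,
                        tol: float = ROOT_TOL) -> int:
    """Number of real roots with |v| > tol."""
    return int(np.sum(np.abs(equilibria_of_v(model, eps)) > tol))


@dataclass(frozen=True)
class BifurcationResult:
    """Threshold eps_star and the root branches on an eps grid."""

    eps_star: float
    eps_grid: np.ndarray
    branches: np.ndarray  # shape (n_eps, 3), NaN-padded
    root_counts: np.ndarray  # nonzero real roots per eps


def bifurcation_threshold(model: ReducedModel, eps_hi: float = 0.25,
                          rel_tol: float = 1e-3, eps_lo: float = 1e-8,
                          n_branch: int = 61) -> BifurcationResult:
    """eps at which the count of nonzero real equilibria changes.

    Bisects (in log eps) on the nonzero-real-root count between ``eps_lo``
    and ``eps_hi`` down to relative tolerance ``rel_tol``; the endpoint
    counts must differ.  Also returns the root branches on a log-spaced grid
    for a bifurcation-diagram export.
    """
    n_lo = count_nonzero_roots(model, eps_lo)
    n_hi = count_nonzero_roots(model, eps_hi)
    if n_lo == n_hi:
        raise ReductionError(
            f"root count does not change on [{eps_lo:g}, {eps_hi:g}] "
            f"(count {n_lo} at both ends)"
        )
    lo, hi = eps_lo, eps_hi
    while hi / lo > 1.0 + rel_tol:
        mid = float(np.sqrt(lo * hi))
        if count_nonzero_roots(model, mid) == n_lo:
            lo = mid
        else:
            hi = mid
    eps_star = float(np.sqrt(lo * hi))

    grid = np.logspace(np.log10(eps_lo), np.log10(eps_hi), n_branch)
    branches = np.full((n_branch, 3), np.nan)
    counts = np.zeros(n_branch, dtype=int)
    for k, e in enumerate(grid):
        roots = equilibria_of_v(model, float(e))
        nz = roots[np.abs(roots) > ROOT_TOL]
        counts[k] = nz.size
        branches[k, :nz.size] = nz[:3]
    return BifurcationResult(eps_star=eps_star, eps_grid=grid,
                             branches=branches, root_counts=counts)
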