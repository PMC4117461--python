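"""Core two-variable fluctuation model of cofactor-driven signaling.

The model tracks two concentrations of the same signaling protein: ``X``,
bound to a non-hydrolyzed (active) cofactor such as ATP/GTP, and ``Z``, bound
to the hydrolyzed (inactive) form.  Because protein encounters are
diffusion-limited, the effective kinetic coefficients ``D1`` (assembly of X to
the receptor complex R), ``D4`` (X-X interaction) and ``D5`` (X-Z interaction)
inherit a linear sensitivity to concentration fluctuations; those
sensitivities (the coefficients ``a`` .. ``f``) are the sole source of
nonlinearity.  The dynamical variables are the fluctuations ``(x, z)`` of the
concentrations about the steady state ``(X_s, Z_s)``, and the control
parameter is the external supply level ``p`` of active cofactor.

This module defines the parameter set, the steady state, the quadratic
fluctuation vector field, its linearization, and the linear-stability estimate
of the critical supply level ``p_c`` at which the quiescent state loses
stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict, fields

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParameters",
    "SteadyState",
    "LinearOperator",
    "validate_params",
    "steady_state",
    "field_coefficients",
    "rhs_fluctuation",
    "linearize",
    "critical_p_linear",
    "fig2_parameters",
    "FIG2_PANEL_P",
]

#: The eight panel values of the supply level swept in the reference
#: simulation figure.
FIG2_PANEL_P = (0.795, 0.81, 0.84, 0.88, 0.96, 1.00, 1.12, 1.16)


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the fluctuation vector field.

    Attributes
    ----------
    D1, D4, D5 : float
        Diffusion-limited kinetic coefficients: assembly of X to the receptor
        complex R, X-X interaction, and X-Z interaction (model units).
    k2 : float
        Hydrolysis rate constant of the bound cofactor.
    a, b : float
        Fluctuation sensitivities of ``D1`` with respect to x and z.
    c, d : float
        Fluctuation sensitivities of ``D4``.
    e, f : float
        Fluctuation sensitivities of ``D5``.
    p : float
        Supply level of active cofactor (the control parameter).
    R : float
        Receptor/oligomer concentration, held constant.
    """

    D1: float
    D4: float
    D5: float
    k2: float
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    p: float
    R: float

    def validate(self) -> "ModelParameters":
        """Check the invariants; return ``self`` unchanged if they hold."""
        for name in ("D1", "D4", "D5", "k2", "R"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("a", "b", "c", "d", "e", "f"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be nonnegative, got {v!r}")
        if not math.isfinite(self.p):
            raise ValueError(f"p must be finite, got {self.p!r}")
        if self.D1 * self.p - self.D5 * self.k2 <= 0:
            raise ValueError(
                "D1*p - D5*k2 must be positive (the denominator of the Z "
                "steady state, D1*(D1*p - D5*k2), must be positive): "
                f"D1*p = {self.D1 * self.p:.6g} <= D5*k2 = {self.D5 * self.k2:.6g}"
            )
        return self

    def with_p(self, p: float) -> "ModelParameters":
        """A copy of this parameter set at a different supply level."""
        return replace(self, p=float(p))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        """Build from a flat mapping; unknown keys are rejected."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(data)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()}).validate()


@dataclass(frozen=True)
class SteadyState:
    """Base-point concentrations about which fluctuations are defined."""

    X_s: float
    Z_s: float


@dataclass(frozen=True)
class LinearOperator:
    """The 2x2 linearization L of the fluctuation field at the origin."""

    L11: float
    L12: float
    L21: float
    L22: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.L11, self.L12], [self.L21, self.L22]], dtype=float)

    @property
    def det(self) -> float:
        return self.L11 * self.L22 - self.L12 * self.L21

    @property
    def trace(self) -> float:
        return self.L11 + self.L22


def validate_params(params: ModelParameters) -> ModelParameters:
    """Validate a parameter set (see :meth:`ModelParameters.validate`)."""
    return params.validate()


def fig2_parameters(p: float = 1.0253) -> ModelParameters:
    """The reference parameter set of the published simulation.

    All constants except ``p`` are fixed; ``p`` is the swept control
    parameter (default: the value printed in the reference program).
    """
    return ModelParameters(
        D1=0.28, D4=156.0, D5=156.0, k2=0.00034580,
        a=800.0, b=656.0, c=100.0, d=100.0, e=100.0, f=100.0,
        p=p, R=1.0,
    ).validate()


def _steady_state_values(params: ModelParameters, p=None):
    """Closed-form steady state; accepts a complex ``p`` override.

    The complex-valued path exists so that derivatives with respect to p can
    be taken by complex-step differentiation (used by the stability
    reduction).
    """
    if p is None:
        p = params.p
    D1, D4, D5, k2, R = params.D1, params.D4, params.D5, params.k2, params.R
    X = k2 / D1
    Z = (k2 * (D1**2 * R + D4 * k2)) / (D1 * (D1 * p - D5 * k2))
    return X, Z


def steady_state(params: ModelParameters) -> SteadyState:
    """Steady state: X_s = k2/D1, Z_s = k2(D1^2 R + D4 k2)/(D1(D1 p - D5 k2))."""
    params.validate()
    X, Z = _steady_state_values(params)
    return SteadyState(X_s=X, Z_s=Z)


def field_coefficients(params: ModelParameters, ss: SteadyState, p=None):
    """Polynomial coefficients of the fluctuation vector field.

    Returns ``(cx, cz)``: two dicts mapping monomial exponents ``(i, j)`` of
    ``x**i * z**j`` to coefficients of dx/dt and dz/dt respectively.  The
    field is quadratic and has no constant term (the origin is an exact
    equilibrium).  ``p`` may override ``params.p`` (complex allowed, for
    complex-step differentiation).
    """
    if p is None:
        p = params.p
    D4, D5, R = params.D4, params.D5, params.R
    D1, a, b, c, d, e, f = (params.D1, params.a, params.b, params.c,
                            params.d, params.e, params.f)
    X, Z = ss.X_s, ss.Z_s
    cx = {
        (1, 0): -(R * (D1 - a * X) + 2 * X * D4 + D5 * Z),
        (2, 0): R * a - D4 + 2 * c * X + e * Z,
        (0, 1): p - D5 * X - b * X - d * X**2 - f * X * Z,
        (1, 1): -(D5 + R * b - e * X + f * Z),
        (0, 2): -(f * X),
    }
    cz = {
        (1, 0): 2 * X * D4 + D5 * Z - c * X**2 - e * X * Z,
        (2, 0): D4 - 2 * c * X - e * Z,
        (1, 1): D5 + 2 * X * d - e * X + f * Z,
        (0, 1): D5 * X - p + d * X**2 + f * X * Z,
    }
    return cx, cz


def rhs_fluctuation(params: ModelParameters, ss: SteadyState, state) -> tuple:
    """Right-hand side (dx/dt, dz/dt) of the fluctuation kinetics.

    ``state`` is the fluctuation pair ``(x, z)``.  Every term carries a factor
    of x or z, so the origin is an exact equilibrium.
    """
    x, z = state
    if not (math.isfinite(x) and math.isfinite(z)):
        raise ValueError(f"non-finite fluctuation state {state!r}")
    cx, cz = field_coefficients(params, ss)
    dx = (cx[(1, 0)] * x + cx[(2, 0)] * x * x + cx[(0, 1)] * z
          + cx[(1, 1)] * x * z + cx[(0, 2)] * z * z)
    dz = (cz[(1, 0)] * x + cz[(2, 0)] * x * x + cz[(1, 1)] * x * z
          + cz[(0, 1)] * z)
    return dx, dz


def linearize(params: ModelParameters, ss: SteadyState) -> LinearOperator:
    """Coefficient matrix of the degree-1 terms of the fluctuation field."""
    cx, cz = field_coefficients(params, ss)
    return LinearOperator(L11=cx[(1, 0)], L12=cx[(0, 1)],
                          L21=cz[(1, 0)], L22=cz[(0, 1)])


def _det_at(params: ModelParameters, p: float) -> float:
    q = params.with_p(p).validate()
    return linearize(q, steady_state(q)).det


def critical_p_linear(params: ModelParameters, p_lo: float, p_hi: float,
                      xtol: float = 1e-6) -> float:
    """Supply level at which the origin loses linear stability.

    Locates the root of ``det L(p) = 0`` on ``[p_lo, p_hi]`` by bracketing
    (Brent), recomputing the steady state at every trial p.  For this model
    the trace of L stays negative through the onset, so the determinant sign
    change is the loss of stability.

    Raises
    ------
    ValueError
        If the determinant does not change sign on the bracket (the error
        message reports both endpoint determinants).
    """
    d_lo, d_hi = _det_at(params, p_lo), _det_at(params, p_hi)
    if d_lo == 0.0:
        return float(p_lo)
    if d_hi == 0.0:
        return float(p_hi)
    if np.sign(d_lo) == np.sign(d_hi):
        raise ValueError(
            "det L(p) does not change sign on the bracket: "
            f"det L({p_lo}) = {d_lo:.6g}, det L({p_hi}) = {d_hi:.6g}"
        )
    return float(brentq(lambda p: _det_at(params, p), p_lo, p_hi, xtol=xtol))
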