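"""Closed-form first-order (order-epsilon) traveling-wave solution.

The first-order fields are superpositions of the acoustic ``nu``-mode and the
viscous ``beta``-mode,

.. math::

    U_1(y) &= \\frac{i\\alpha}{\\nu} c_1 \\cosh\\nu y
              + \\frac{i\\beta}{\\alpha} c_2 \\cosh\\beta y, \\\\
    V_1(y) &= c_1 \\sinh\\nu y + c_2 \\sinh\\beta y, \\\\
    P_1(y) &= \\frac{\\nu^2-\\beta^2}{\\gamma\\nu} c_1 \\cosh\\nu y,

with the complex amplitudes ``c1`` (acoustic) and ``c2`` (viscous) fixed by
the wall conditions ``U1(+-1) = 0`` and ``V1(+-1) = -+ i alpha / 2`` (the
conditions at the two walls are equivalent by parity, so a 2x2 complex solve
at one wall suffices).

Evaluation uses wall-normalized hyperbolics ``cosh(k y)/cosh(k)`` and
``sinh(k y)/cosh(k)`` so that strongly damped or strongly oscillatory modes
(``|beta| ~ 1e3 .. 1e4`` at large ``reynolds * lambda1``) never overflow: all
stored amplitudes are the field values scaled to the wall, and every
exponential evaluated has a non-positive real part.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularSystemError
from .modes import ModeConstants, derive_mode_constants
from .params import FlowParameters

_DOMAIN_TOL = 1e-12


def _check_domain(y: np.ndarray) -> np.ndarray:
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(np.abs(y) > 1.0 + _DOMAIN_TOL):
        raise ValueError("y must lie in [-1, 1]")
    return np.clip(y, -1.0, 1.0)


def cosh_ratio(k: complex, y: np.ndarray) -> np.ndarray:
    """cosh(k*y)/cosh(k), overflow-safe for Re(k) >= 0 and |y| <= 1."""
    ya = np.abs(y)
    num = np.exp(k * (ya - 1.0)) * (1.0 + np.exp(-2.0 * k * ya))
    den = 1.0 + np.exp(-2.0 * k)
    return num / den


def sinh_ratio(k: complex, y: np.ndarray) -> np.ndarray:
    """sinh(k*y)/cosh(k), overflow-safe for Re(k) >= 0 and |y| <= 1."""
    ya = np.abs(y)
    num = np.exp(k * (ya - 1.0)) * (1.0 - np.exp(-2.0 * k * ya))
    den = 1.0 + np.exp(-2.0 * k)
    return np.sign(y) * num / den


@dataclass(frozen=True)
class FirstOrderField:
    """First-order complex amplitude functions and their y-derivatives.

    ``c1w`` and ``c2w`` are the wall-scaled amplitudes ``c1 cosh(nu)`` and
    ``c2 cosh(beta)``; the raw ``c1``, ``c2`` are exposed as properties (they
    underflow harmlessly to 0 when a mode is wall-confined beyond double
    range, which is why the scaled form is what everything else uses).
    """

    params: FlowParameters
    constants: ModeConstants
    c1w: complex
    c2w: complex

    @property
    def c1(self) -> complex:
        return self.c1w / np.cosh(self.constants.nu)

    @property
    def c2(self) -> complex:
        return self.c2w / np.cosh(self.constants.beta)

    @property
    def p1w(self) -> complex:
        """Wall-scaled pressure amplitude of the acoustic mode."""
        c = self.constants
        return (c.nu2 - c.beta2) / (c.gamma * c.nu) * self.c1w

    # -- mode coefficient table (wall-scaled), used for evaluation ----------
    def _coeffs(self):
        a = self.params.alpha
        nu, beta = self.constants.nu, self.constants.beta
        u = (1j * a / nu * self.c1w, 1j * beta / a * self.c2w)
        v = (self.c1w, self.c2w)
        p = (self.p1w, 0.0)
        return nu, beta, u, v, p

    def U1(self, y):
        y = _check_domain(y)
        nu, beta, u, _, _ = self._coeffs()
        return u[0] * cosh_ratio(nu, y) + u[1] * cosh_ratio(beta, y)

    def V1(self, y):
        y = _check_domain(y)
        nu, beta, _, v, _ = self._coeffs()
        return v[0] * sinh_ratio(nu, y) + v[1] * sinh_ratio(beta, y)

    def P1(self, y):
        y = _check_domain(y)
        nu, _, _, _, p = self._coeffs()
        return p[0] * cosh_ratio(nu, y)

    def dU1(self, y):
        y = _check_domain(y)
        nu, beta, u, _, _ = self._coeffs()
        return u[0] * nu * sinh_ratio(nu, y) + u[1] * beta * sinh_ratio(beta, y)

    def d2U1(self, y):
        y = _check_domain(y)
        nu, beta, u, _, _ = self._coeffs()
        return u[0] * nu**2 * cosh_ratio(nu, y) + u[1] * beta**2 * cosh_ratio(beta, y)

    def dV1(self, y):
        y = _check_domain(y)
        nu, beta, _, v, _ = self._coeffs()
        return v[0] * nu * cosh_ratio(nu, y) + v[1] * beta * cosh_ratio(beta, y)

    def d2V1(self, y):
        y = _check_domain(y)
        nu, beta, _, v, _ = self._coeffs()
        return v[0] * nu**2 * sinh_ratio(nu, y) + v[1] * beta**2 * sinh_ratio(beta, y)

    def dP1(self, y):
        y = _check_domain(y)
        nu, _, _, _, p = self._coeffs()
        return p[0] * nu * sinh_ratio(nu, y)

    def sample_table(self, y):
        """Field samples as plain columns (y, Re/Im of U1, V1, P1), CSV-ready."""
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = {"y": y}
        for name, fn in (("U1", self.U1), ("V1", self.V1), ("P1", self.P1)):
            z = fn(y)
            out[f"{name}_re"] = z.real
            out[f"{name}_im"] = z.imag
        return out


def solve_mode_amplitudes(
    constants: ModeConstants,
    params: FlowParameters,
    *,
    wall: float = 1.0,
    bc_scale: float = 1.0,
    scaled: bool = False,
):
    """Solve the 2x2 wall-condition system for the mode amplitudes.

    Rows are ``U1(wall) = 0`` and ``V1(wall) = -i alpha wall / 2 * bc_scale``.
    ``wall=-1`` imposes the lower-wall conditions instead (identical result
    by parity; exposed for symmetry checks).  With ``scaled=True`` the
    wall-normalized amplitudes ``(c1 cosh nu, c2 cosh beta)`` are returned.
    """
    if wall not in (1.0, -1.0):
        raise ValueError("wall must be +-1")
    a = params.alpha
    nu, beta = constants.nu, constants.beta
    M = np.array(
        [
            [1j * a / nu * cosh_ratio(nu, wall), 1j * beta / a * cosh_ratio(beta, wall)],
            [sinh_ratio(nu, wall), sinh_ratio(beta, wall)],
        ],
        dtype=complex,
    )
    rhs = np.array([0.0, -1j * a * wall / 2.0 * bc_scale], dtype=complex)
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    norm = np.abs(M).max() ** 2
    if abs(det) < 1e-14 * norm:
        raise SingularSystemError(
            f"wall-condition system singular (|det|={abs(det):.3e}, norm={norm:.3e}) "
            f"at {params.to_mapping()}"
        )
    c1w, c2w = np.linalg.solve(M, rhs)
    if scaled:
        return complex(c1w), complex(c2w)
    return (
        complex(c1w / np.cosh(nu)),
        complex(c2w / np.cosh(beta)),
    )


def solve_first_order(params: FlowParameters, constants: ModeConstants | None = None) -> FirstOrderField:
    """Derive constants (unless given) and solve the wall conditions."""
    if constants is None:
        constants = derive_mode_constants(params)
    c1w, c2w = solve_mode_amplitudes(constants, params, scaled=True)
    return FirstOrderField(params=params, constants=constants, c1w=c1w, c2w=c2w)


def eval_first_order(field: FirstOrderField, y):
    """Evaluate (U1, V1, P1) on ``y`` (thin wrapper around the field methods)."""
    return field.U1(y), field.V1(y), field.P1(y)


def _chebyshev_points(n: int) -> np.ndarray:
    return np.cos(np.pi * np.arange(n) / (n - 1))


def first_order_residual(
    field: FirstOrderField,
    constants: ModeConstants | None = None,
    params: FlowParameters | None = None,
    *,
    n: int = 64,
) -> float:
    """Max relative residual of the first-order system plus wall conditions.

    Evaluated on ``n`` Chebyshev points.  Each equation's residual is
    normalized by the largest magnitude any of its terms attains on the
    sample, so the number is meaningful across the full parameter range
    (including boundary-layer regimes where individual terms are
    ~|beta|^2 times larger than the fields).  The wall-condition residuals
    are normalized by the wall forcing amplitude ``alpha/2``; they are what
    makes the residual respond to a perturbed mode amplitude (any amplitude
    pair solves the interior equations exactly).
    """
    constants = constants or field.constants
    params = params or field.params
    a, chi = params.alpha, params.chi
    g, b2 = constants.gamma, constants.beta2
    y = _chebyshev_points(n)
    U1, V1, P1 = field.U1(y), field.V1(y), field.P1(y)
    dU1, dV1, dP1 = field.dU1(y), field.dV1(y), field.dP1(y)
    d2U1, d2V1 = field.d2U1(y), field.d2V1(y)

    worst = 0.0
    for terms in (
        (dV1, 1j * a * U1, -1j * a * chi * P1),
        (d2U1, -b2 * U1, -1j * a * g * P1),
        (d2V1, -b2 * V1, -g * dP1),
    ):
        r = np.abs(sum(terms)).max()
        scale = max(np.abs(t).max() for t in terms)
        if scale == 0.0:
            continue
        worst = max(worst, r / scale)

    walls = np.array([1.0, -1.0])
    bc_scale = a / 2.0
    bc_u = np.abs(field.U1(walls)).max()
    bc_v = np.abs(field.V1(walls) + 1j * a * walls / 2.0).max()
    worst = max(worst, bc_u / bc_scale, bc_v / bc_scale)
    return worst
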