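"""Order-epsilon^2 time-averaged (streaming) mean flow.

Averaging the governing equations over the traveling-wave phase at second
order in the amplitude ratio gives, for the mean axial velocity ``U20`` and
mean transverse velocity ``V20``:

.. math::

    U_{20}''(y) = R\\, f(y), \\qquad
    V_{20}(y) = -\\chi\\,(P_1\\bar V_1 + \\bar P_1 V_1) + D_1,

where ``f`` collects the averaged quadratic products of the first-order
field.  For the linear Maxwell model the convected contribution vanishes and

.. math:: f(y) = \\frac{d}{dy}\\left(U_1\\bar V_1 + \\bar U_1 V_1\\right),

while the upper convected model adds the relaxation-weighted block

.. math::

    \\lambda_1\\Big\\{ 2\\alpha^2(2U_1\\bar U_1 - U_1\\bar P_1 - \\bar U_1 P_1)
    - (U_1'\\bar P_1' + \\bar U_1' P_1')
    + i\\alpha(2\\bar U_1' V_1 - 2U_1'\\bar V_1
              + \\bar V_1 P_1' - V_1\\bar P_1')\\Big\\},

each term a conjugate pair, so ``f`` is real by construction (the complex
arithmetic is arranged pairwise and the imaginary part is checked before
being discarded).  Two integrations with inner and outer lower limits fixed
at ``y = 0`` give ``E(y)``; this convention keeps ``E`` even (``f`` is even),
which is what makes the odd integration constant ``D2`` vanish and keeps the
mean-velocity perturbation function free of a spurious linear term.

The wall values follow from Taylor-expanding the no-slip/impermeability
conditions at the displaced wall ``y = +-(1 + eta)`` and averaging:
``U20(+-1) = -+Re U1'(+-1)`` and ``V20(+-1) = -+Re V1'(+-1)``.  The
transverse condition determines ``D1``; because ``U1(+-1) = 0`` forces
``chi (P_1 bar V_1 + bar P_1 V_1)(+-1) = +-Re V1'(+-1)`` identically, the
constant comes out ``D1 = 0`` — a consistency that is verified, not assumed.
The axial conditions are a 2x2 solve for ``(D2, D3)`` in
``U20 = R E(y) + D2 y + D3``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_simpson, quad
from scipy.interpolate import CubicSpline

from .errors import ConsistencyError, QuadratureWarning
from .firstorder import FirstOrderField, solve_first_order
from .params import FlowParameters

#: oscillation scale above which the nested integral switches from adaptive
#: quadrature to a dense composite grid (the integrand then has ~k/pi
#: oscillations per unit length and pointwise adaptivity stops paying off)
GRID_SWITCH_SCALE = 40.0
_IMAG_RTOL = 1e-10


def _real_checked(z: np.ndarray, what: str) -> np.ndarray:
    scale = np.abs(z.real).max() if z.size else 0.0
    bad = np.abs(z.imag).max() if z.size else 0.0
    if bad > _IMAG_RTOL * max(scale, 1e-300):
        raise ConsistencyError(
            f"{what}: imaginary residue {bad:.3e} exceeds {_IMAG_RTOL:g} x magnitude {scale:.3e}"
        )
    return z.real.copy() if np.iscomplexobj(z) else np.asarray(z, dtype=float)


def mean_forcing_f(field: FirstOrderField, params: FlowParameters | None = None, y=None) -> np.ndarray:
    """Mean axial forcing ``f(y)``; variant-dependent (UCM adds the
    relaxation block, linear Maxwell omits it entirely)."""
    params = params or field.params
    y = np.atleast_1d(np.asarray(y, dtype=float))
    a, l1 = params.alpha, params.lambda1
    U1, V1, P1 = field.U1(y), field.V1(y), field.P1(y)
    dU1, dV1, dP1 = field.dU1(y), field.dV1(y), field.dP1(y)
    cU1, cV1, cP1 = np.conj(U1), np.conj(V1), np.conj(P1)
    cdU1, cdV1, cdP1 = np.conj(dU1), np.conj(dV1), np.conj(dP1)

    # d/dy (U1 conj(V1) + conj(U1) V1), expanded with analytic derivatives
    f = dU1 * cV1 + U1 * cdV1 + cdU1 * V1 + cU1 * dV1
    if params.is_ucm and l1 > 0.0:
        block = (
            2 * a * a * (2 * U1 * cU1 - U1 * cP1 - cU1 * P1)
            - (dU1 * cdP1 + cdU1 * dP1)
            + 1j * a * (2 * cdU1 * V1 - 2 * dU1 * cV1 + cV1 * dP1 - V1 * cdP1)
        )
        f = f + l1 * block
    return _real_checked(f, "mean forcing f")


@dataclass(frozen=True)
class NestedIntegral:
    """The double integral ``E(y) = int_0^y int_0^s f`` and derived values."""

    E: Callable[[np.ndarray], np.ndarray]
    Eprime: Callable[[np.ndarray], np.ndarray]
    E1: float
    integral01: float  #: int_0^1 E(y) dy, used by the net flow rate
    method: str

    def __call__(self, y):
        return self.E(y)


def _integrate_E_quad(f_vec: Callable, tol: float) -> NestedIntegral:
    limit = 200

    def f(s):
        return float(np.asarray(f_vec(s)).reshape(-1)[0])

    def _q(func, lo, hi):
        val, err = quad(func, lo, hi, epsabs=tol, epsrel=tol, limit=limit)
        if err > 100 * max(tol, tol * abs(val)):
            warnings.warn(
                f"quadrature error estimate {err:.2e} above tolerance {tol:.1e}",
                QuadratureWarning,
                stacklevel=3,
            )
        return val

    def E(y):
        ys = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.array([_q(lambda s, yy=yy: (yy - s) * float(f(s)), 0.0, yy) for yy in ys])
        return out if np.ndim(y) else float(out[0])

    def Eprime(y):
        ys = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.array([_q(lambda s: float(f(s)), 0.0, yy) for yy in ys])
        return out if np.ndim(y) else float(out[0])

    E1 = float(E(1.0))
    integral01 = _q(lambda s: float(f(s)) * (1.0 - s) ** 2 / 2.0, 0.0, 1.0)
    return NestedIntegral(E=E, Eprime=Eprime, E1=E1, integral01=integral01, method="quad")


def _integrate_E_grid(f: Callable, scale: float) -> NestedIntegral:
    n_half = int(2 ** np.ceil(np.log2(max(4096.0, 40.0 * scale))))
    n_half = min(n_half, 2**21)
    y = np.linspace(-1.0, 1.0, 2 * n_half + 1)
    i0 = n_half
    fs = np.asarray(f(y), dtype=float)
    c1 = cumulative_simpson(fs, x=y, initial=0.0)
    ep = c1 - c1[i0]
    c2 = cumulative_simpson(ep, x=y, initial=0.0)
    e = c2 - c2[i0]
    e_spl = CubicSpline(y, e)
    ep_spl = CubicSpline(y, ep)
    # Simpson over [0, 1] on the same grid
    from scipy.integrate import simpson

    integral01 = float(simpson(e[i0:], x=y[i0:]))
    return NestedIntegral(
        E=lambda yy: e_spl(yy),
        Eprime=lambda yy: ep_spl(yy),
        E1=float(e[-1]),
        integral01=integral01,
        method="grid",
    )


def integrate_E(
    f: Callable,
    *,
    method: str = "auto",
    oscillation_scale: float = 1.0,
    tol: float = 1e-10,
) -> NestedIntegral:
    """Nested integral of the mean forcing, lower limits fixed at ``y = 0``.

    ``method='quad'`` uses adaptive quadrature (absolute tolerance ``tol``);
    ``method='grid'`` a dense composite-Simpson grid whose resolution scales
    with ``oscillation_scale`` (the largest mode wavenumber magnitude —
    strongly elastic regimes make ``f`` oscillate on the ``1/|beta|`` scale).
    ``'auto'`` picks quadrature below :data:`GRID_SWITCH_SCALE`.
    """
    if method == "auto":
        method = "quad" if oscillation_scale <= GRID_SWITCH_SCALE else "grid"
    if method == "quad":
        return _integrate_E_quad(f, tol)
    if method == "grid":
        return _integrate_E_grid(f, oscillation_scale)
    raise ValueError(f"unknown method {method!r}")


def _wall_product(field: FirstOrderField, y) -> np.ndarray:
    """chi-weighted conjugate pair ``P1 conj(V1) + conj(P1) V1`` at ``y``."""
    P1 = field.P1(y)
    V1 = field.V1(y)
    return _real_checked(P1 * np.conj(V1) + np.conj(P1) * V1, "P1*conj(V1) pair")


def solve_transverse_constant(field: FirstOrderField, params: FlowParameters | None = None,
                              *, tol: float = 1e-8) -> float:
    """Determine ``D1`` from the averaged transverse wall conditions.

    Imposing ``V20(w) = -w Re V1'(w)`` at both walls gives one value of
    ``D1`` per wall; they must agree (and equal zero, by the identity
    ``chi Pi(1) = Re V1'(1)`` that follows from ``U1(+-1) = 0``).  A
    disagreement beyond ``tol`` raises :class:`ConsistencyError`.
    """
    params = params or field.params
    chi = params.chi
    walls = np.array([1.0, -1.0])
    pi_w = _wall_product(field, walls)
    target = -walls * np.real(field.dV1(walls))
    d1_each = target + chi * pi_w
    scale = max(1.0, float(np.abs(chi * pi_w).max()))
    if np.abs(d1_each[0] - d1_each[1]) > tol * scale:
        raise ConsistencyError(
            f"transverse wall conditions disagree: D1(+1)={d1_each[0]:.3e}, "
            f"D1(-1)={d1_each[1]:.3e}"
        )
    return float(d1_each.mean())


def mean_transverse_V20(field: FirstOrderField, params: FlowParameters | None = None,
                        y=None, *, D1: float | None = None) -> np.ndarray:
    """Mean transverse velocity ``V20(y) = -chi (P1 conj(V1) + c.c.) + D1``."""
    params = params or field.params
    if D1 is None:
        D1 = solve_transverse_constant(field, params)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    return -params.chi * _wall_product(field, y) + D1


def solve_wall_constants(field: FirstOrderField, E: NestedIntegral,
                         params: FlowParameters | None = None) -> tuple[float, float]:
    """Solve the averaged axial wall conditions for ``(D2, D3)``.

    ``U20(w) + w Re U1'(w) = 0`` at ``w = +-1`` is a 2x2 linear system in
    ``(D2, D3)`` (matrix rows ``[w, 1]``); it is never singular.
    """
    params = params or field.params
    R = params.reynolds
    walls = np.array([1.0, -1.0])
    targets = -walls * np.real(field.dU1(walls)) - R * np.asarray(E(walls), dtype=float)
    A = np.column_stack([walls, np.ones(2)])
    D2, D3 = np.linalg.solve(A, targets)
    return float(D2), float(D3)


def mean_axial_U20(E: NestedIntegral, D2: float, D3: float,
                   params: FlowParameters, y) -> np.ndarray:
    """Mean axial velocity ``U20(y) = R E(y) + D2 y + D3``."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    return params.reynolds * np.asarray(E(y), dtype=float) + D2 * y + D3


@dataclass(frozen=True)
class SecondOrderField:
    """Bundled mean-flow solution for one parameter point."""

    params: FlowParameters
    first_order: FirstOrderField
    E: NestedIntegral
    D1: float
    D2: float
    D3: float

    def f(self, y):
        return mean_forcing_f(self.first_order, self.params, y)

    def V20(self, y):
        return mean_transverse_V20(self.first_order, self.params, y, D1=self.D1)

    def U20(self, y):
        return mean_axial_U20(self.E, self.D2, self.D3, self.params, y)

    def wall_condition_residuals(self) -> dict[str, float]:
        """Absolute residuals of the four averaged wall conditions."""
        walls = np.array([1.0, -1.0])
        ru = self.U20(walls) + walls * np.real(self.first_order.dU1(walls))
        rv = self.V20(walls) + walls * np.real(self.first_order.dV1(walls))
        return {
            "U20_wall": float(np.abs(ru).max()),
            "V20_wall": float(np.abs(rv).max()),
        }


def solve_second_order(
    params: FlowParameters,
    first_order: FirstOrderField | None = None,
    *,
    method: str = "auto",
    tol: float = 1e-10,
) -> SecondOrderField:
    """First-order solve + mean-flow quadrature + wall constants, bundled."""
    fo = first_order or solve_first_order(params)
    kmax = max(abs(fo.constants.beta), abs(fo.constants.nu), 1.0)
    f = lambda y: mean_forcing_f(fo, params, y)
    E = integrate_E(f, method=method, oscillation_scale=kmax, tol=tol)
    D1 = solve_transverse_constant(fo, params)
    D2, D3 = solve_wall_constants(fo, E, params)
    return SecondOrderField(params=params, first_order=fo, E=E, D1=D1, D2=D2, D3=D3)
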