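"""Complex constants of the two first-order traveling-wave modes.

Writing every first-order field as ``X1(y) exp(i alpha (x - t)) + c.c.`` and
eliminating the density through the equation of state, the linearized
conservation laws reduce to

.. math::

    V_1' + i\\alpha U_1 &= i\\alpha\\chi P_1, \\\\
    U_1'' - \\beta^2 U_1 &= i\\alpha\\gamma P_1, \\\\
    V_1'' - \\beta^2 V_1 &= \\gamma P_1',

with the modified inertia coefficient ``gamma = (1 - i a l1) R - i a chi / 3``
and the viscous-mode wavenumber ``beta**2 = a**2 - i a (1 - i a l1) R``
(``a = alpha``, ``R = reynolds``, ``l1 = lambda1``).  The homogeneous
solution splits into two y-symmetric modes:

* the *viscous* (shear) mode ``cosh(beta y) / sinh(beta y)`` carrying no
  pressure, and
* the *acoustic* (compressible) mode ``cosh(nu y) / sinh(nu y)``, whose
  wavenumber ``nu`` is fixed by the compatibility relation obtained by
  substituting the mode into all three equations simultaneously:

.. math::

    \\gamma(\\nu^2 - \\alpha^2) = i\\alpha\\chi(\\nu^2 - \\beta^2)
    \\quad\\Longleftrightarrow\\quad
    \\nu^2 = \\frac{\\gamma\\alpha^2 - i\\alpha\\chi\\beta^2}{\\gamma - i\\alpha\\chi}.

As ``chi -> 0`` the acoustic mode continuously deforms to the incompressible
pressure mode, ``nu -> alpha``.  The pressure amplitude of the nu-mode is
``P_1 = (nu^2 - beta^2) / (gamma nu) * c_1 cosh(nu y)``; the normalization
factor ``xi`` in that prefactor equals ``gamma``.

Square roots take the branch with non-negative real part (ties broken toward
positive imaginary part); the hyperbolic mode shapes are even/odd, so fields
are branch independent, but a fixed branch keeps outputs reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModeError
from .params import FlowParameters

#: relative |nu - beta| threshold below which the closed form is rejected
DEGENERACY_RTOL = 1e-8


def _principal_sqrt(z: complex) -> complex:
    """Square root with Re >= 0; purely imaginary results take Im > 0."""
    r = complex(np.sqrt(complex(z)))
    if r.real < 0 or (r.real == 0 and r.imag < 0):
        r = -r
    return r


@dataclass(frozen=True)
class ModeConstants:
    """Complex constants defining the first-order modes for one parameter set."""

    gamma: complex
    beta2: complex
    beta: complex
    nu: complex
    xi: complex

    @property
    def nu2(self) -> complex:
        return self.nu * self.nu

    def to_jsonable(self) -> dict:
        out = {}
        for name in ("gamma", "beta2", "beta", "nu", "xi"):
            z = getattr(self, name)
            out[f"{name}_re"] = z.real
            out[f"{name}_im"] = z.imag
        return out


def gamma_coefficient(params: FlowParameters) -> complex:
    a, R, chi, l1 = params.alpha, params.reynolds, params.chi, params.lambda1
    return (1 - 1j * a * l1) * R - 1j * a * chi / 3


def beta_squared(params: FlowParameters) -> complex:
    a, R, l1 = params.alpha, params.reynolds, params.lambda1
    return a * a - 1j * a * (1 - 1j * a * l1) * R


def nu_squared(params: FlowParameters) -> complex:
    g = gamma_coefficient(params)
    b2 = beta_squared(params)
    a, chi = params.alpha, params.chi
    return (g * a * a - 1j * a * chi * b2) / (g - 1j * a * chi)


def compatibility_residual(nu: complex, params: FlowParameters) -> float:
    """Relative residual of the acoustic-mode compatibility relation.

    Zero (to rounding) iff ``nu`` solves
    ``gamma (nu^2 - alpha^2) = i alpha chi (nu^2 - beta^2)``.
    """
    g = gamma_coefficient(params)
    b2 = beta_squared(params)
    a, chi = params.alpha, params.chi
    lhs = g * (nu * nu - a * a)
    rhs = 1j * a * chi * (nu * nu - b2)
    scale = max(abs(lhs), abs(rhs), abs(g) * a * a)
    return abs(lhs - rhs) / scale


def derive_mode_constants(params: FlowParameters) -> ModeConstants:
    """Derive ``gamma``, ``beta``, ``nu`` and ``xi`` for a parameter set.

    Raises
    ------
    DegenerateModeError
        If the two mode wavenumbers coalesce (``|nu - beta|`` below
        ``DEGENERACY_RTOL * |beta|``); the closed form is then invalid.
    """
    g = gamma_coefficient(params)
    b2 = beta_squared(params)
    beta = _principal_sqrt(b2)
    nu = _principal_sqrt(nu_squared(params))
    xi = g  # pressure normalization factor of the nu-mode
    for name, z in (("gamma", g), ("beta", beta), ("nu", nu)):
        if not (np.isfinite(z.real) and np.isfinite(z.imag)):
            raise FloatingPointError(f"non-finite {name} at {params.to_mapping()}")
    if abs(nu - beta) < DEGENERACY_RTOL * abs(beta):
        raise DegenerateModeError(
            f"mode coalescence |nu - beta| < {DEGENERACY_RTOL:g}|beta| at "
            f"{params.to_mapping()}: nu={nu}, beta={beta}"
        )
    return ModeConstants(gamma=g, beta2=b2, beta=beta, nu=nu, xi=xi)
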