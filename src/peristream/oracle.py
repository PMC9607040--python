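"""Independent numerical ground truth for the first-order solution.

The closed form in :mod:`peristream.firstorder` is validated against a
direct collocation solution of the first-order boundary-value problem.  The
system is written in the complex state ``(U1, U1', V1, P1)``:

.. math::

    U_1'' &= \\beta^2 U_1 + i\\alpha\\gamma P_1, \\\\
    V_1'  &= -i\\alpha U_1 + i\\alpha\\chi P_1, \\\\
    P_1'  &= -\\frac{i\\alpha U_1' + \\beta^2 V_1}{\\gamma - i\\alpha\\chi},

where the ``P1'`` relation follows from eliminating ``V1''`` between the
transverse momentum equation and the differentiated continuity equation
(this stays regular at ``chi = 0``, where the acoustic mode degenerates to
the incompressible pressure mode).  Four boundary conditions,
``U1(+-1) = 0`` and ``V1(+-1) = -+ i alpha/2``, close the fourth-order
system.  Collocation (not shooting) is used because the viscous mode is a
wall boundary layer of width ``1/|beta|``; shooting would overflow in the
stiff regimes.

The module also carries a deliberately simple composite-rule nested
integrator used by tests as an independent check of the adaptive mean-flow
quadrature.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_bvp

from .errors import ConvergenceError
from .firstorder import FirstOrderField
from .modes import derive_mode_constants
from .params import FlowParameters


@dataclass(frozen=True)
class OracleSolution:
    """Collocation solution samples of the first-order system."""

    params: FlowParameters
    y: np.ndarray
    U1: np.ndarray
    V1: np.ndarray
    P1: np.ndarray
    max_residual: float
    converged: bool
    n_nodes: int

    def sample_table(self):
        return {
            "y": self.y,
            "U1_re": self.U1.real, "U1_im": self.U1.imag,
            "V1_re": self.V1.real, "V1_im": self.V1.imag,
            "P1_re": self.P1.real, "P1_im": self.P1.imag,
        }


def solve_first_order_bvp(
    params: FlowParameters,
    tol: float = 1e-10,
    *,
    n_initial: int | None = None,
    max_nodes: int = 200_000,
) -> OracleSolution:
    """Solve the first-order BVP by adaptive collocation.

    ``tol`` is the collocation residual tolerance passed to the mesh
    refinement (must be in (0, 1e-4]).  The initial mesh density scales with
    ``|beta|`` so boundary layers and transverse oscillations are resolved
    from the first iteration.
    """
    if not 0.0 < tol <= 1e-4:
        raise ValueError("tol must lie in (0, 1e-4]")
    consts = derive_mode_constants(params)
    a, chi = params.alpha, params.chi
    g, b2 = consts.gamma, consts.beta2
    den = g - 1j * a * chi
    kmax = max(abs(consts.beta), abs(consts.nu), 1.0)
    if n_initial is None:
        n_initial = int(min(20_001, max(401, 16 * kmax)))

    def rhs(y, z):
        U1 = z[0] + 1j * z[1]
        dU = z[2] + 1j * z[3]
        V1 = z[4] + 1j * z[5]
        P1 = z[6] + 1j * z[7]
        d2U = b2 * U1 + 1j * a * g * P1
        dV = -1j * a * U1 + 1j * a * chi * P1
        dP = -(1j * a * dU + b2 * V1) / den
        return np.vstack([
            dU.real, dU.imag, d2U.real, d2U.imag,
            dV.real, dV.imag, dP.real, dP.imag,
        ])

    def bc(zl, zr):
        Ul, Ur = zl[0] + 1j * zl[1], zr[0] + 1j * zr[1]
        Vl, Vr = zl[4] + 1j * zl[5], zr[4] + 1j * zr[5]
        res = [Ul, Ur, Vl - 1j * a / 2.0, Vr + 1j * a / 2.0]
        return np.array([q for c in res for q in (c.real, c.imag)])

    y0 = np.linspace(-1.0, 1.0, n_initial)
    z0 = np.zeros((8, n_initial))
    z0[5] = -a / 2.0 * y0  # odd Im(V1) ramp matching the wall forcing
    sol = solve_bvp(rhs, bc, y0, z0, tol=tol, max_nodes=max_nodes)
    if not sol.success:
        raise ConvergenceError(
            f"collocation failed ({sol.message}) at {params.to_mapping()}"
        )
    y = sol.x
    z = sol.y
    return OracleSolution(
        params=params,
        y=y,
        U1=z[0] + 1j * z[1],
        V1=z[4] + 1j * z[5],
        P1=z[6] + 1j * z[7],
        max_residual=float(np.max(sol.rms_residuals)),
        converged=bool(sol.success),
        n_nodes=len(y),
    )


def project_mode_amplitudes(oracle: OracleSolution) -> tuple[complex, complex]:
    """Extract (c1, c2) from an oracle solution by least-squares projection.

    The sampled (U1, V1) profiles are regressed onto the two closed-form
    mode shapes; with an accurate oracle this recovers the amplitudes the
    direct 2x2 wall solve produces, providing an independent route to them.
    """
    consts = derive_mode_constants(oracle.params)
    a = oracle.params.alpha
    nu, beta = consts.nu, consts.beta
    y = oracle.y
    A = np.concatenate([
        np.column_stack([1j * a / nu * np.cosh(nu * y), 1j * beta / a * np.cosh(beta * y)]),
        np.column_stack([np.sinh(nu * y), np.sinh(beta * y)]),
    ])
    b = np.concatenate([oracle.U1, oracle.V1])
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return complex(coef[0]), complex(coef[1])


def brute_force_double_integral(f_samples, y) -> np.ndarray:
    """Nested integral ``E(y) = int_0^y int_0^s f`` by repeated trapezoid.

    ``y`` must be a dense monotone grid containing 0 (>= 257 points); both
    the inner and the outer integration start at y = 0, matching the
    convention of the adaptive integrator it cross-checks.  Test-only
    helper: simple by design, so its failure modes are independent of the
    production path.
    """
    y = np.asarray(y, dtype=float)
    f_samples = np.asarray(f_samples)
    if y.ndim != 1 or y.size < 257:
        raise ValueError("need a dense 1-D grid (>= 257 points)")
    if not np.any(np.isclose(y, 0.0, atol=1e-14)):
        raise ValueError("grid must contain y = 0")
    i0 = int(np.argmin(np.abs(y)))
    inner = cumulative_trapezoid(f_samples, y, initial=0.0)
    inner = inner - inner[i0]
    outer = cumulative_trapezoid(inner, y, initial=0.0)
    return outer - outer[i0]
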