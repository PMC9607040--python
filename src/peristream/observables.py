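"""Reported observables of the mean flow.

* ``G(y)``: the mean-velocity perturbation function, a normalized steady
  axial profile ``G(y) = scale_G * (E(y) - E(1))`` on [0, 1] with
  ``G(1) = 0`` by construction.  The default normalization is
  ``scale_G = -200 / (alpha^2 R^2)``; the printed source form is ambiguous
  between this ratio and the product ``-200 alpha^2 R^2``, so the
  alternative reading is selectable (``g_scale_reading='product'``) for
  sensitivity checks.  All shape/sign conclusions are scale independent up
  to the overall sign, which both readings share.
* ``<u>(y) = epsilon^2 U20(y)``: the mean axial velocity.
* ``<Q> = epsilon^2 int_0^1 U20 dy``: the dimensionless net flow rate.
* ``D_wall = U20(1)``: the induced steady slip velocity at the wall.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .params import FlowParameters
from .secondorder import NestedIntegral, SecondOrderField, solve_second_order

DEFAULT_Y_POINTS = 201


def g_scale(params: FlowParameters, reading: str = "ratio") -> float:
    """Normalization constant of the perturbation function.

    ``'ratio'`` (default): ``-200 / (alpha^2 R^2)``; ``'product'``:
    ``-200 alpha^2 R^2`` (the alternative reading of the ambiguous source).
    """
    a2R2 = (params.alpha * params.reynolds) ** 2
    if reading == "ratio":
        return -200.0 / a2R2
    if reading == "product":
        return -200.0 * a2R2
    raise ValueError(f"unknown g_scale reading {reading!r}")


def perturbation_G(E: NestedIntegral, params: FlowParameters, y,
                   *, g_scale_reading: str = "ratio") -> np.ndarray:
    """Mean-velocity perturbation profile ``G(y)`` on ``y`` in [0, 1]."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any((y < -1e-12) | (y > 1.0 + 1e-12)):
        raise ValueError("G is defined on y in [0, 1]")
    return g_scale(params, g_scale_reading) * (np.asarray(E(y), dtype=float) - E.E1)


def net_flow_rate(so: SecondOrderField, params: FlowParameters | None = None) -> float:
    """Net flow rate ``<Q> = eps^2 int_0^1 U20`` via the solved quadrature.

    ``int_0^1 U20 = R int_0^1 E + D2/2 + D3`` reuses the nested integral's
    own ``int_0^1 E`` (adaptive or dense-grid, matching how ``E`` was
    built), so no additional quadrature error enters.
    """
    params = params or so.params
    integral = params.reynolds * so.E.integral01 + so.D2 / 2.0 + so.D3
    return params.epsilon**2 * integral


def d_wall(so: SecondOrderField) -> float:
    """Steady axial slip at the wall, ``U20(1)``."""
    return float(so.U20(1.0)[0])


@dataclass(frozen=True)
class Observables:
    """Sampled observables for one parameter point."""

    params: FlowParameters
    y: np.ndarray
    G: np.ndarray        #: perturbation profile on the y >= 0 half grid
    mean_u: np.ndarray   #: eps^2 U20 on the full y grid
    Q: float
    d_wall: float
    second_order: SecondOrderField

    def to_jsonable(self) -> dict:
        return {
            "params": self.params.to_mapping(),
            "Q": self.Q,
            "d_wall": self.d_wall,
            "D1": self.second_order.D1,
            "D2": self.second_order.D2,
            "D3": self.second_order.D3,
        }


def compute_observables(
    params: FlowParameters,
    *,
    n_y: int = DEFAULT_Y_POINTS,
    g_scale_reading: str = "ratio",
    method: str = "auto",
) -> Observables:
    """Solve one parameter point end to end and sample the observables."""
    so = solve_second_order(params, method=method)
    y_full = np.linspace(-1.0, 1.0, n_y)
    y_half = np.linspace(0.0, 1.0, n_y)
    G = perturbation_G(so.E, params, y_half, g_scale_reading=g_scale_reading)
    mean_u = params.epsilon**2 * so.U20(y_full)
    return Observables(
        params=params,
        y=y_full,
        G=G,
        mean_u=mean_u,
        Q=net_flow_rate(so, params),
        d_wall=d_wall(so),
        second_order=so,
    )
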