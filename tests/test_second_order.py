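import numpy as np
import pytest

from peristream import (
    FlowParameters,
    integrate_E,
    mean_axial_U20,
    mean_forcing_f,
    mean_transverse_V20,
    net_flow_rate,
    solve_first_order,
    solve_second_order,
    solve_transverse_constant,
    solve_wall_constants,
)

Y = np.linspace(0.0, 1.0, 41)


def test_forcing_is_even(rep_first_order, rep_params):
    f_pos = mean_forcing_f(rep_first_order, rep_params, Y)
    f_neg = mean_forcing_f(rep_first_order, rep_params, -Y)
    assert np.abs(f_pos - f_neg).max() < 1e-10 * np.abs(f_pos).max()


def test_forcing_variants_identical_without_relaxation():
    base = dict(alpha=0.5, reynolds=10.0, chi=0.3, lambda1=0.0)
    f_lin = mean_forcing_f(solve_first_order(FlowParameters(**base, variant="LINEAR")), y=Y)
    f_ucm = mean_forcing_f(solve_first_order(FlowParameters(**base, variant="UCM")), y=Y)
    assert np.array_equal(f_lin, f_ucm)


def test_forcing_variants_differ_with_relaxation(rep_params):
    f_ucm = mean_forcing_f(solve_first_order(rep_params), y=Y)
    lin = rep_params.with_(variant="LINEAR")
    f_lin = mean_forcing_f(solve_first_order(lin), y=Y)
    assert np.abs(f_ucm - f_lin).max() > 1e-3 * np.abs(f_lin).max()


def test_newtonian_forcing_matches_finite_differences(rep_first_order, rep_params):
    """The d/dy(U1 conj(V1) + c.c.) part, evaluated with analytic
    derivatives, agrees with central differences of the product."""
    lin = rep_params.with_(variant="LINEAR")
    fo = solve_first_order(lin)
    y = np.linspace(-0.9, 0.9, 21)
    h = 1e-5
    prod = lambda yy: np.real(fo.U1(yy) * np.conj(fo.V1(yy))) * 2
    fd = (prod(y + h) - prod(y - h)) / (2 * h)
    f = mean_forcing_f(fo, lin, y)
    assert np.abs(f - fd).max() < 1e-6 * max(1.0, np.abs(f).max())


@pytest.mark.parametrize(
    "f,E_exact,E1",
    [
        (lambda y: np.ones_like(np.asarray(y, dtype=float)), lambda y: y**2 / 2, 0.5),
        (lambda y: np.cos(np.pi * np.asarray(y, dtype=float)),
         lambda y: (1 - np.cos(np.pi * y)) / np.pi**2, 2 / np.pi**2),
    ],
    ids=["constant", "cosine"],
)
@pytest.mark.parametrize("method", ["quad", "grid"])
def test_nested_integral_closed_forms(f, E_exact, E1, method):
    E = integrate_E(f, method=method)
    y = np.linspace(-1.0, 1.0, 21)
    assert np.abs(np.asarray(E(y)) - E_exact(y)).max() < 1e-9
    assert abs(E.E1 - E1) < 1e-9


def test_nested_integral_methods_agree_on_physical_forcing(rep_first_order, rep_params):
    f = lambda y: mean_forcing_f(rep_first_order, rep_params, y)
    Eq = integrate_E(f, method="quad")
    Eg = integrate_E(f, method="grid", oscillation_scale=10.0)
    y = np.linspace(-1.0, 1.0, 31)
    assert np.abs(np.asarray(Eq(y)) - np.asarray(Eg(y))).max() < 1e-8
    assert abs(Eq.integral01 - Eg.integral01) < 1e-8


def test_zero_forcing_leaves_wall_slip_flow(rep_params):
    """f == 0 collapses U20 to the constant fixed by the wall conditions."""
    E0 = integrate_E(lambda y: np.zeros_like(np.asarray(y, dtype=float)), method="quad")
    fo = solve_first_order(rep_params)
    D2, D3 = solve_wall_constants(fo, E0, rep_params)
    U20 = mean_axial_U20(E0, D2, D3, rep_params, Y)
    assert abs(D2) < 1e-12
    assert np.abs(U20 - D3).max() == 0.0
    assert abs(D3 + np.real(fo.dU1(1.0)[0])) < 1e-12


def test_transverse_constant_vanishes(rep_first_order, rep_params):
    assert abs(solve_transverse_constant(rep_first_order, rep_params)) < 1e-10


def test_transverse_wall_identity(rep_first_order, rep_params):
    """chi * (P1 conj(V1) + c.c.)(1) equals Re V1'(1): the identity (via
    U1(1)=0 and continuity) that makes D1 = 0 exactly."""
    w = np.array([1.0])
    pi1 = np.real(rep_first_order.P1(w) * np.conj(rep_first_order.V1(w))) * 2
    lhs = rep_params.chi * pi1[0]
    rhs = np.real(rep_first_order.dV1(w))[0]
    assert abs(lhs - rhs) < 1e-12 * max(abs(rhs), 1e-30)


def test_mean_transverse_odd_and_zero_at_center(rep_second_order):
    v = rep_second_order.V20(Y)
    v_neg = rep_second_order.V20(-Y)
    assert np.abs(v + v_neg).max() < 1e-12 * max(np.abs(v).max(), 1e-30)
    assert abs(rep_second_order.V20(0.0)[0]) < 1e-14


def test_incompressible_mean_transverse_vanishes():
    p = FlowParameters(alpha=0.5, reynolds=10.0, chi=0.0, lambda1=0.5)
    fo = solve_first_order(p)
    v = mean_transverse_V20(fo, p, Y)
    assert np.abs(v).max() == 0.0


def test_wall_constants_and_parity(rep_second_order):
    so = rep_second_order
    assert abs(so.D1) < 1e-10
    assert abs(so.D2) < 1e-10
    res = so.wall_condition_residuals()
    assert res["U20_wall"] < 1e-10
    assert res["V20_wall"] < 1e-10
    u = so.U20(Y)
    assert np.abs(u - so.U20(-Y)).max() < 1e-9 * max(np.abs(u).max(), 1.0)


def test_mean_flow_is_real(rep_second_order):
    assert rep_second_order.f(Y).dtype.kind == "f"
    assert rep_second_order.U20(Y).dtype.kind == "f"
    assert rep_second_order.V20(Y).dtype.kind == "f"


def test_amplitude_ratio_scaling_is_exactly_quadratic(rep_params):
    """<u> and <Q> carry the eps^2 factor exactly."""
    small = solve_second_order(rep_params.with_(epsilon=0.1))
    large = solve_second_order(rep_params.with_(epsilon=0.2))
    q_small = net_flow_rate(small)
    q_large = net_flow_rate(large)
    assert q_large == pytest.approx(4.0 * q_small, rel=0, abs=0)
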