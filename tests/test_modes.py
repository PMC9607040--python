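import itertools

import numpy as np
import pytest

import peristream.modes as modes
from peristream import (
    DegenerateModeError,
    FlowParameters,
    compatibility_residual,
    derive_mode_constants,
)


def _grid_10x10x10x10():
    alphas = np.linspace(0.05, 2.0, 10)
    reynolds = np.geomspace(1.0, 1e4, 10)
    chis = np.linspace(0.0, 0.8, 10)
    lambda1s = np.linspace(0.0, 10.0, 10)
    return itertools.product(alphas, reynolds, chis, lambda1s)


def test_beta_squared_identity_on_dense_grid():
    """beta is an exact square root of a^2 - i a (1 - i a l1) R everywhere."""
    worst = 0.0
    for a, R, chi, l1 in _grid_10x10x10x10():
        c = derive_mode_constants(FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=l1))
        target = a * a - 1j * a * (1 - 1j * a * l1) * R
        worst = max(worst, abs(c.beta * c.beta - target) / abs(target))
    assert worst < 1e-14


def test_nu_satisfies_compatibility_relation_on_dense_grid():
    worst = 0.0
    for a, R, chi, l1 in _grid_10x10x10x10():
        p = FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=l1)
        worst = max(worst, compatibility_residual(derive_mode_constants(p).nu, p))
    assert worst < 1e-10


def test_branch_choice_real_parts_nonnegative():
    for a, R, chi, l1 in _grid_10x10x10x10():
        c = derive_mode_constants(FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=l1))
        assert c.beta.real >= 0
        assert c.nu.real >= 0


@pytest.mark.parametrize("name", ["alpha", "reynolds", "chi", "lambda1"])
def test_constants_continuous_along_parameter_sweeps(name):
    """No branch jumps: constants vary smoothly along fine 1-D sweeps."""
    base = dict(alpha=0.5, reynolds=10.0, chi=0.3, lambda1=0.5)
    spans = {
        "alpha": np.linspace(0.05, 2.0, 400),
        "reynolds": np.geomspace(1.0, 1e4, 400),
        "chi": np.linspace(0.0, 0.8, 400),
        "lambda1": np.linspace(0.0, 10.0, 400),
    }
    vals = []
    for v in spans[name]:
        c = derive_mode_constants(FlowParameters(**{**base, name: float(v)}))
        vals.append([c.beta, c.nu, c.gamma])
    vals = np.array(vals)
    for k in range(vals.shape[1]):
        z = vals[:, k]
        step = np.abs(np.diff(z))
        scale = np.maximum(np.abs(z[:-1]), np.abs(z[1:]))
        assert np.all(step < 0.2 * scale + 1e-12)


def test_newtonian_limit_matches_lambda1_zero_formulas():
    """At l1 = 0, gamma and beta^2 reduce to the Newtonian specialization,
    and the variant flag has no effect on the constants."""
    a, R, chi = 0.7, 50.0, 0.4
    lin = derive_mode_constants(
        FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=0.0, variant="LINEAR"))
    ucm = derive_mode_constants(
        FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=0.0, variant="UCM"))
    assert lin == ucm
    assert lin.gamma == R - 1j * a * chi / 3
    assert lin.beta2 == a * a - 1j * a * R


def test_incompressible_limit_of_acoustic_mode():
    """As chi -> 0 the acoustic wavenumber tends to alpha.

    Cross-checked against an independent root of the dispersion polynomial
    in nu^2 (np.roots) at chi = 1e-8 and 1e-10, Richardson-extrapolated in
    chi to the incompressible point.
    """
    a, R, l1 = 0.5, 10.0, 0.5

    def poly_root(chi):
        p = FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=l1)
        g = modes.gamma_coefficient(p)
        b2 = modes.beta_squared(p)
        # gamma (nu2 - a^2) - i a chi (nu2 - b2) = 0, linear polynomial in nu2
        coeffs = [g - 1j * a * chi, -(g * a * a - 1j * a * chi * b2)]
        (nu2,) = np.roots(coeffs)
        nu = np.sqrt(nu2)
        return nu if nu.real >= 0 else -nu

    n8, n10 = poly_root(1e-8), poly_root(1e-10)
    # roots are linear in chi near 0: Richardson eliminates the O(chi) term
    extrapolated = n10 + (n10 - n8) / (1e-8 / 1e-10 - 1)
    nu0 = derive_mode_constants(
        FlowParameters(alpha=a, reynolds=R, chi=0.0, lambda1=l1)).nu
    assert abs(nu0 - a) < 1e-12
    assert abs(extrapolated - nu0) < 1e-9


def test_mode_coalescence_raises(monkeypatch):
    p = FlowParameters(alpha=0.5, reynolds=10.0, chi=0.3, lambda1=0.5)
    b2 = modes.beta_squared(p)
    monkeypatch.setattr(modes, "nu_squared", lambda _p: b2 * (1 + 1e-10))
    with pytest.raises(DegenerateModeError):
        modes.derive_mode_constants(p)


def test_constants_serialize_with_split_parts():
    c = derive_mode_constants(FlowParameters(alpha=0.5, reynolds=10.0, chi=0.3))
    d = c.to_jsonable()
    assert d["beta_re"] == c.beta.real and d["beta_im"] == c.beta.imag
    assert set(d) == {f"{n}_{p}" for n in ("gamma", "beta2", "beta", "nu", "xi")
                      for p in ("re", "im")}
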