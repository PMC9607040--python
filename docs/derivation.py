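"""Symbolic derivation record for the mean-flow forcing.

Runnable standalone (``python docs/derivation.py``; needs sympy, ~2 min).
It expands the upper convected Maxwell axial momentum balance

    (1 + l1 D/Dt)[ rho (u_t + u u_x + v u_y) + p_x ]
        = (1/R) (lap u + (1/3) d_x (u_x + v_y))

through second order in the amplitude ratio ``eps``, with the traveling-wave
representation ``q = eps (Q1(y) e^{i th} + c.c.) + eps^2 q20(y)
+ eps^2 (Q22 e^{2 i th} + c.c.)``, ``th = alpha (x - t)``, the exponential
equation of state ``rho = exp(chi p)`` expanded to second order, and
``D/Dt`` the contravariant convected derivative of a vector field.  The
phase average of the ``eps^2`` terms must reduce to ``u20''/R = f(y)``.

Two identities are verified (both print ``0``):

1. the phase-averaged expansion equals the hand-derived forcing ``f_raw``
   built from the first-order amplitudes with no substitutions;
2. after substituting the first-order continuity relation
   ``V1' = i alpha (chi P1 - U1)``, ``f_raw`` equals the compact form used
   by :func:`peristream.secondorder.mean_forcing_f`:

       f = d/dy(U1 cV1 + cU1 V1)
           + l1 { 2 a^2 (2 U1 cU1 - U1 cP1 - cU1 P1)
                  - (U1' cP1' + cU1' P1')
                  + i a (2 cU1' V1 - 2 U1' cV1 + cV1 P1' - V1 cP1') }

   This fixes the sign/prime placement of the relaxation block: the pair
   ``U1' cP1' - cU1' P1'`` sometimes quoted for this class of problems is
   purely imaginary (it would drop from any real mean), and the correct
   combination is the conjugate pair with a minus sign; likewise the
   ``2 cU1' V1`` term carries a prime on the conjugate axial amplitude.
"""
import sympy as sp

y, th, al, l1, chi, R, eps = sp.symbols("y theta alpha lambda1 chi R epsilon",
                                        real=True, positive=True)
I = sp.I


def cpair(name):
    r = sp.Function(name + "r", real=True)(y)
    i = sp.Function(name + "i", real=True)(y)
    return r + I * i, r - I * i


U1, cU1 = cpair("U")
V1, cV1 = cpair("V")
P1, cP1 = cpair("P")
Uh, cUh = cpair("Uh")   # second harmonic (drops from the phase average)
Vh, cVh = cpair("Vh")
Ph, cPh = cpair("Ph")
u20 = sp.Function("u20", real=True)(y)
v20 = sp.Function("v20", real=True)(y)
p20 = sp.Function("p20", real=True)(y)

E = sp.exp(I * th)


def field(X1, cX1, x20, X2, cX2):
    return eps * (X1 * E + cX1 / E) + eps**2 * (x20 + X2 * E**2 + cX2 / E**2)


u = field(U1, cU1, u20, Uh, cUh)
v = field(V1, cV1, v20, Vh, cVh)
p = field(P1, cP1, p20, Ph, cPh)
rho = 1 + chi * p + chi**2 * p**2 / 2   # exp EOS through O(eps^2)


def Dx(q):
    return al * sp.diff(q, th)


def Dt(q):
    return -al * sp.diff(q, th)


def Dy(q):
    return sp.diff(q, y)


ax = rho * (Dt(u) + u * Dx(u) + v * Dy(u)) + Dx(p)
ay = rho * (Dt(v) + u * Dx(v) + v * Dy(v)) + Dy(p)
# contravariant convected derivative, x-component, of the vector (ax, ay)
Dax = Dt(ax) + u * Dx(ax) + v * Dy(ax) - Dx(u) * ax - Dy(u) * ay

lhs = ax + l1 * Dax
rhs = (Dx(Dx(u)) + Dy(Dy(u)) + sp.Rational(1, 3) * Dx(Dx(u) + Dy(v))) / R

expr = sp.expand(sp.series(sp.expand(lhs - rhs), eps, 0, 3).removeO())
mean = sp.expand(sp.integrate(expr.coeff(eps, 2), (th, 0, 2 * sp.pi)) / (2 * sp.pi))

d = lambda q: sp.diff(q, y)

# hand-derived phase-averaged forcing, no substitutions
axN = I * al * chi * (P1 * cU1 - cP1 * U1) + (V1 * d(cU1) + cV1 * d(U1))
A = I * al * (P1 - U1)          # first-order x-acceleration amplitude
B, cB = d(P1) - I * al * V1, d(cP1) + I * al * cV1
T14 = 2 * I * al * (A * cU1 + I * al * (cP1 - cU1) * U1)
T2 = I * al * (cV1 * d(P1) - cV1 * d(U1) - V1 * d(cP1) + V1 * d(cU1))
T5 = -(d(U1) * cB + d(cU1) * B)
f_raw = axN + l1 * (T14 + T2 + T5)

check1 = sp.simplify(sp.expand(mean - (f_raw - sp.diff(u20, y, 2) / R)))
print("phase-averaged expansion minus (f_raw - u20''/R):", check1)

# compact form actually implemented
f_impl = d(U1 * cV1 + cU1 * V1) + l1 * (
    2 * al**2 * (2 * U1 * cU1 - U1 * cP1 - cU1 * P1)
    - (d(U1) * d(cP1) + d(cU1) * d(P1))
    + I * al * (2 * d(cU1) * V1 - 2 * d(U1) * cV1 + cV1 * d(P1) - V1 * d(cP1))
)
sub = {d(V1): I * al * (chi * P1 - U1), d(cV1): -I * al * (chi * cP1 - cU1)}
check2 = sp.simplify(sp.expand(f_impl.subs(sub) - f_raw.subs(sub)))
print("implemented forcing minus f_raw (continuity substituted):", check2)
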