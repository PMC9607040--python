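# Methods

## Problem and expansion

A two-dimensional channel of half-width 1 (dimensionless) carries a
traveling sinusoidal wall wave `η = ε cos(α(x − t))` on both walls
(symmetric deformation).  The fluid is compressible
(`ρ = exp(χ(p − p₀))`) and viscoelastic: a Maxwell element with relaxation
time `λ₁`, either with a partial time derivative in the stress relaxation
equation (**linear** variant) or with the frame-invariant contravariant
convected derivative (**UCM** variant).  The momentum balance is treated in
the usual way for this family of streaming problems: the relaxation
operator `(1 + λ₁D/Dt)` is applied to the whole momentum equation so the
stress divergence reduces to the Newtonian form; `D/Dt` acting on the
acceleration-plus-pressure-gradient vector uses the contravariant convected
derivative.  Mass conservation is
`ρₜ + uρₓ + vρ_y + ρ(uₓ + v_y) = 0` and the deviatoric stress uses the
compressible (Stokes) form, giving the `(1/3)∇(∇·V)` viscous term.

All fields are expanded in the amplitude ratio `ε`, with the first order
written as a single traveling harmonic `X₁(y)e^{iα(x−t)} + c.c.`; the wall
displacement `ε cos` therefore carries amplitude `ε/2` per complex
exponential, which fixes the first-order wall conditions `U₁(±1) = 0`,
`V₁(±1) = ∓iα/2`.

## First order: two-mode closed form

Eliminating the density by the equation of state gives the sixth-order-in-
appearance, fourth-order-in-fact system quoted in the README, with

- `γ = (1 − iαλ₁)R − iαχ/3` (modified inertia),
- `β² = α² − iα(1 − iαλ₁)R` (viscous/shear mode),
- `ν² = (γα² − iαχβ²)/(γ − iαχ)` (acoustic mode, from the compatibility
  relation `γ(ν² − α²) = iαχ(ν² − β²)`).

The acoustic-mode pressure amplitude is
`P₁ = (ν² − β²)/(γν)·c₁ cosh νy`; the `ν`-mode limits to the
incompressible pressure mode (`ν → α`) as `χ → 0`, which is the branch
selection criterion.  Square roots take `Re ≥ 0` (ties toward `Im > 0`);
fields are branch independent because the mode shapes are even/odd.

Numerical choices:

- **Wall-scaled hyperbolics.**  All evaluation uses
  `cosh(ky)/cosh(k)` and `sinh(ky)/cosh(k)` computed from exponentials
  with non-positive real part.  In strongly elastic regimes
  (`R = 10⁴, λ₁ = 10⁴`) `|β|` reaches `2·10⁴` and naive `cosh` would
  overflow at `|β| ≳ 710`.
- **Amplitude solve.**  One 2×2 complex solve at `y = +1` (the `y = −1`
  conditions are automatic by parity; solving there instead changes
  nothing, which is tested).  Determinant below `10⁻¹⁴ ×` matrix norm
  raises `SingularSystemError`; `|ν − β| < 10⁻⁸|β|` raises
  `DegenerateModeError` before that.
- **Residual gate.**  The quality metric is the max relative residual of
  the three field equations (each normalized by the largest magnitude among
  its own terms) plus the wall-condition residuals normalized by `α/2`.
  The closed form sits at `~10⁻¹⁵`; the acceptance gate is `10⁻⁸`.

## Collocation oracle

An independent check solves the boundary-value problem directly with
`scipy.integrate.solve_bvp` on the complex state `(U₁, U₁′, V₁, P₁)` split
into real and imaginary parts.  `P₁′` is obtained by eliminating `V₁″`
between transverse momentum and differentiated continuity,
`P₁′ = −(iαU₁′ + β²V₁)/(γ − iαχ)`, which stays regular at `χ = 0`.
Collocation is used instead of shooting because the viscous mode is a wall
boundary layer of width `1/|β|`.  The initial mesh density scales as
`16|β|`; the mesh tolerance is `10⁻⁹` in moderate regimes and relaxed to
`10⁻⁶` when `max(|β|,|ν|) > 50`, where refinement is oscillation-limited —
the observed agreement with the closed form is then still `≲ 10⁻⁹`,
comfortably inside the `10⁻⁶` cross-validation gate used over the full
figure-caption grid (`α ∈ {0.1, 0.5, 1}`, `R ∈ {10, 100, 10⁴}`,
`χ ∈ {0.001, 0.3, 0.6}`, `λ₁ ∈ {0, 0.5, 5}`).

## Second order: mean flow

The phase-averaged axial momentum balance at `O(ε²)` reduces to
`U₂₀″ = R f(y)` with no mean pressure gradient (free pumping, periodic in
`x`).  The forcing was derived symbolically (`docs/derivation.py` expands
the full UCM momentum equation through `O(ε²)` with sympy and verifies the
implemented form term by term):

```
f = d/dy(U₁V̄₁ + Ū₁V₁)
  + λ₁{ 2α²(2U₁Ū₁ − U₁P̄₁ − Ū₁P₁)
        − (U₁′P̄₁′ + Ū₁′P₁′)
        + iα(2Ū₁′V₁ − 2U₁′V̄₁ + V̄₁P₁′ − V₁P̄₁′) }
```

Every term is a conjugate pair, so `f` is real; the implementation builds
it pairwise and raises if the imaginary residue exceeds `10⁻¹⁰` of the
magnitude.  Two printed forms of this block in the source literature are
not conjugate pairs (one is purely imaginary and would vanish from any real
mean; another lacks a prime); the derivation fixes the intended
combinations, and this is the single most consequential interpretation in
the package — see *Discrepancies* below.

For the **linear** variant the braced block is absent entirely (the
convected terms are quadratic, so at first order the two models coincide;
`λ₁ > 0` with the linear variant still enters `γ` and `β²`).

**Nested integral.**  `E(y) = ∬f`, inner and outer lower limits at
`y = 0`.  Because `f` is even this makes `E` even and `E′` odd — the only
convention consistent with the symmetric channel; any other lower limit
shifts `D₂, D₃` but would contaminate `G(y) = scale·(E(y) − E(1))` with a
spurious linear term.  Two integration paths:

- adaptive quadrature (`scipy.integrate.quad`, absolute tolerance `10⁻¹⁰`,
  `QuadratureWarning` if the error estimate is out of range) when
  `max(|β|,|ν|) ≤ 40`;
- a dense composite-Simpson grid otherwise (resolution `40×` the largest
  mode wavenumber, capped at `2²¹` intervals; cubic-spline readout), since
  the forcing then oscillates on the `1/|β|` scale and pointwise adaptivity
  is wasted.  Flow-rate integrals reuse the same grid.  Convergence was
  verified by 16× refinement (`⟨Q⟩` stable to 7 digits in the worst,
  `λ₁ = 10⁴`, regime).

A simple trapezoid-in-trapezoid integrator (`brute_force_double_integral`)
provides the independent cross-check in tests.

**Wall conditions.**  Taylor-expanding the moving-wall conditions and
averaging gives `U₂₀(±1) = ∓Re U₁′(±1)` and `V₂₀(±1) = ∓Re V₁′(±1)`.
The transverse condition fixes `D₁`; the identity
`χ(P₁V̄₁ + P̄₁V₁)(±1) = ±Re V₁′(±1)` (a direct consequence of
`U₁(±1) = 0` and continuity) makes `D₁ = 0` exactly, and the code verifies
rather than assumes this (`ConsistencyError` beyond `10⁻⁸`).  Note that
`V₂₀(±1)` itself is *not* zero for `χ > 0`: the mean transverse velocity
at the mean wall line balances the wave-correlated mass flux.  The axial
conditions are a never-singular 2×2 solve for `(D₂, D₃)`; parity forces
`D₂ = 0` (tested, not imposed).  A structural consequence worth stating:
`D_wall = U₂₀(1) = −Re U₁′(1)` depends only on the first-order field and
is therefore **identical for the linear and UCM variants** at equal
parameters.

## Observables

`G(y) = −200/(α²R²)·(E(y) − E(1))` on `[0, 1]` (so `G(1) = 0` exactly);
the printed normalization is ambiguous between this ratio and the product
`−200α²R²`, so the alternative is selectable
(`g_scale_reading="product"`), and no conclusion in the package depends on
the absolute scale.  `⟨u⟩ = ε²U₂₀`, `⟨Q⟩ = ε²∫₀¹U₂₀ dy` (reusing the
solved quadrature), `D_wall = U₂₀(1)`.  `ε` enters only through the exact
`ε²` prefactor, which is tested bit-for-bit.

## Sweeps and recipes

The `fig2` … `fig9` recipes transcribe the caption parameters of the source
parametric studies.  Captions do not print the legend lists of relaxation
times; the defaults are documented choices:

- order-unity `λ₁` (0–5) for the `R = 10 … 100` studies, spanning weak to
  strong elasticity at those Reynolds numbers;
- `λ₁ ∈ {0, 0.001, 0.002, 0.005}` for the `R = 10⁴` flow-rate study: the
  elastic scale there is `αλ₁R`, so order-unity `λ₁` is deep in the
  resonant regime where `⟨Q⟩(α)` oscillates violently, and smooth
  single-valued curves of the kind that study shows exist only for
  `αλ₁R = O(10)`.

Default sweep abscissa `α ∈ [0.01, 2]` (200 points) straddles all reported
landmarks (0.07, 0.08, 0.75).

## Discrepancies with the reported trends

The analytic layer (residual gates, oracle equivalence, limits, parity,
`D₁ = D₂ = 0`, `ε²` scaling) validates completely.  Of the reported
qualitative trends, these reproduce: linear-model centerline `G` magnitude
decreasing in `λ₁`; Newtonian `G` flat over the half width (≤ 5% at
`R = 100`, where the statement is made — at `R = 10` the boundary layer
spans the channel and the profile is not flat); wall slip increasing with
`χ` (linear); UCM near-wall backflow at strong relaxation; variant-agreement
of `⟨Q⟩` below `α ≈ 0.75` with the linear branch increasing beyond it; and
oscillatory `⟨Q⟩(α)` with UCM negative excursions at `λ₁ = 10⁴`.

These do not, under the re-derived formulas, and are left as failing
acceptance checks rather than tuned away:

- **UCM-specific `D_wall` behavior** (negative, decreasing with `χ`):
  impossible structurally, since `U₂₀(1) = −Re U₁′(1)` is variant
  independent (see above).  Both variants show the *linear*-model behavior.
- **Centerline `G` trends for UCM**: the magnitude first dips (the signed
  value crosses zero near `λ₁ ≈ 0.8` at the `R = 10` study point) before
  growing, so it is not monotonically increasing over the default legend,
  and the linear-vs-UCM magnitude ordering holds only for `λ₁ ≲ 0.5` (the
  two curves cross).
- **`⟨u⟩` increasing with `λ₁`**: at the `R = 10`, `χ = 0.05` study point
  the centerline mean velocity *decreases* with `λ₁` for both variants.
- **UCM `⟨Q⟩` decreasing beyond `α = 0.75`** at `R = 10⁴`: the UCM curve
  keeps increasing wherever the small-`α` variant agreement holds; notably
  the computed ordering `⟨Q⟩_UCM > ⟨Q⟩_LIN` at larger `α` matches what the
  same authors report for the axisymmetric-tube version of this problem.
- **`λ₁ = 10⁴` flow rate**: the linear-model `⟨Q⟩` oscillates through both
  signs (it is dominated by the resonant wall-slip term `−Re U₁′(1)`),
  so neither "positive throughout" nor variant-independence below
  `α = 0.07` holds.

Given that the source's printed equations contain several internal
inconsistencies that had to be repaired before any solution existed (the
continuity equation's velocity-gradient typo and missing compressibility
factor, a non-conjugate-pair forcing block, a pressure normalization that
satisfies no grouping of its printed form), the failing trends most likely
reflect those same defects propagated into the source's own numerics.  All
numbers behind the failures come from converged, cross-validated
computation.

## Limitations

Symmetric sinusoidal wall waves only; no mean pressure gradient (free
pumping); second-harmonic `ε²` components and `O(ε³)` corrections are not
computed; dimensionless in/out only.  The model is two-dimensional and
says nothing about axisymmetric tubes.  Physiological realism is limited
by the single-relaxation-time Maxwell rheology and the barotropic
exponential equation of state.
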