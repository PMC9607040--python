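# peristream

Steady streaming driven by peristaltic waves in a compressible Maxwell
fluid, in a two-dimensional flexible-wall microchannel.

Physiological conduits and acoustically driven microfluidic channels
transport fluid by traveling waves of wall deformation.  When the fluid is
compressible and viscoelastic (blood is the motivating example), the
oscillatory first-order flow rectifies into a steady second-order mean flow
whose direction and magnitude depend sensitively on the stress relaxation
time and the compressibility.  `peristream` computes this mean flow
analytically, for both the **linear Maxwell** and the **upper convected
Maxwell (UCM)** constitutive models, and ships an independent numerical
oracle that validates every closed form.  It is aimed at researchers in
biofluid mechanics and microfluidic acoustic streaming who need reproducible
reference solutions and parametric sweeps.

## Model

Channel of half-width `h`, walls at `y = ±(1 + η)` with
`η = ε cos(α(x − t))` (lengths scaled by `h`, velocities by the wave speed
`c`).  Dimensionless groups: wave number `α`, Reynolds number
`R = ρ₀ch/μ`, compressibility `χ` (equation of state
`ρ = exp(χ(p − p₀))`), relaxation time `λ₁`, and amplitude ratio
`ε ≪ 1`, the perturbation parameter.

A regular expansion in `ε` with fields `X₁(y)e^{iα(x−t)} + c.c.` gives the
first-order system

```
V₁′ + iαU₁ = iαχP₁
U₁″ − β²U₁ = iαγP₁         γ  = (1 − iαλ₁)R − iαχ/3
V₁″ − β²V₁ = γP₁′          β² = α² − iα(1 − iαλ₁)R
```

solved in closed form by a viscous mode `cosh βy` and an acoustic mode
`cosh νy`, with `ν² = (γα² − iαχβ²)/(γ − iαχ)` and amplitudes fixed by
`U₁(±1) = 0`, `V₁(±1) = ∓iα/2`.  Averaging over the wave phase at order
`ε²` yields the mean flow

```
U₂₀″ = R f(y),   U₂₀ = R E(y) + D₂y + D₃,   E = ∬ f dy dy
V₂₀  = −χ(P₁V̄₁ + P̄₁V₁) + D₁           (D₁ = 0)
```

where `f(y)` is the averaged quadratic forcing (the UCM variant adds a
`λ₁`-weighted convected block, re-derived symbolically in
`docs/derivation.py`).  Reported observables: the mean-velocity
perturbation function `G(y) = −200/(α²R²)·(E(y) − E(1))`, the mean axial
velocity `⟨u⟩ = ε²U₂₀`, the net flow rate `⟨Q⟩ = ε²∫₀¹U₂₀ dy`, and the
wall streaming slip `D_wall = U₂₀(1)`.

## Worked example

One parameter point from the library:

```python
from peristream import FlowParameters, compute_observables

p = FlowParameters(alpha=0.5, reynolds=10, chi=0.3, lambda1=0.5,
                   epsilon=0.1, variant="UCM")
obs = compute_observables(p)
print(obs.Q, obs.d_wall)
```

or from the shell:

```sh
peristream solve --alpha 0.5 -R 10 --chi 0.3 --lambda1 0.5
```

which prints (abridged):

```json
{
  "Q": 0.023219673409101412,
  "d_wall": 2.219201939175464,
  "D1": 0.0,
  "D2": 0.0,
  "D3": 2.3086185513975424,
  "mode_constants": {
    "beta_re": 1.4316108957382214, "beta_im": -1.7462845577958914,
    "nu_re": 0.4187842736572633,  "nu_im": -0.0016692125971741912
  }
}
```

Reading: the viscous mode decays from the wall on the scale
`1/Re(β) ≈ 0.7` while the acoustic mode (`ν ≈ 0.42`) fills the channel;
the wave drags a positive steady slip `D_wall ≈ 2.22` (in units of
`ε²c`), the integration constants of the mean flow are `D₁ = D₂ = 0` as
parity requires, and the net flow rate `⟨Q⟩ ≈ 0.0232` at `ε = 0.1` pumps
in the direction of wave propagation.

Parametric studies (the shipped recipes `fig2` … `fig9` encode the source
figure captions):

```sh
peristream sweep --recipe fig5 --out fig5.csv
peristream figures --csv fig5.csv --out-dir figures/
```

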