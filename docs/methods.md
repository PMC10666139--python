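# Methods

## Model

`coregrm` solves the one-dimensional, isothermal, nonlinear general rate
model (GRM) of liquid chromatography for beds packed with core–shell
(superficially porous) particles carrying two classes of adsorption sites.

All quantities are dimensionless: axial position `x ∈ [0,1]` over the column
length, time `ξ` in units of the space time `L/u_int` (interstitial velocity
`u_int = u/ε_b`), bead radial position `ϑ ∈ [ϑ_core, 1]` over the bead
radius, and concentrations scaled by a reference feed concentration.

**Bulk phase** (per solute `i`):

```
∂c_b/∂ξ + ∂c_b/∂x = (1/Pe) ∂²c_b/∂x² − 3 Bi η F_b (c_b − c_p|ϑ=1)
```

with the bed phase ratio `F_b = (1−ε_b)/ε_b`, the column-length Peclet
number `Pe = L u_int / D_ax`, the Biot number `Bi = k_ext R_p/(ε_p D_p)` and
`η = ε_p D_p L/(R_p² u_int)`, the ratio of space time to intraparticle
diffusion time.  The factor `3 Bi η F_b` is the unique film grouping that
balances the particle-side surface flux exactly (discrete mass conservation
to round-off).

**Particle phase.**  The porous shell stores solute in the pore liquid and
on the surface; the inert core is impenetrable.  Writing the bi-Langmuir
equilibrium loading

```
q_i*(c) = a_i^I c_i / (1 + Σ_j b_j^I c_j) + a_i^II c_i / (1 + Σ_j b_j^II c_j)
```

the shell balance on `ϑ ∈ [ϑ_core, 1]` is

```
∂/∂ξ [ ε_p c_p,i + q_i*(c_p) ] = η_i (1/ϑ²) ∂/∂ϑ ( ϑ² ∂c_p,i/∂ϑ )
```

with zero flux at the core interface and the film Robin condition
`∂c_p/∂ϑ|₁ = Bi (c_b − c_p|₁)` at the bead surface.  Danckwerts boundary
conditions close the bulk equation: the total inlet-face flux equals
`c_inj` during the rectangular pulse `0 ≤ ξ < ξ_inj` and zero afterwards,
and the outlet is zero-gradient.

**Capacity convention.**  Two conventions appear in the literature for the
accumulation term: the Henry constants may describe loading per unit *solid*
volume (then the isotherm enters as `(1−ε_p) q*`) or per unit *particle*
volume (then it enters as `q*` directly, as above).  This package adopts the
per-particle-volume reading: with the reference constants
(`a^I+a^II = 25/65/145` for solutes one/two/three) it reproduces the
characteristic linear-limit retention times
`ξ_R = 1 + F_b (1−ϑ_core³)(ε_p + a^I + a^II)` ≈ 99 / 219 for the two- and
three-component mixtures — i.e. complete-elution windows of roughly 100 and
200 for fully porous beds, dropping to about 40–50 and 95–110 at
`ϑ_core = 0.8` — which is the regime these scenarios are designed to
represent.  Both conventions were implemented and compared during
development; the alternative halves every retention window.  Published
tabulations that mix conventions (or derive collection windows from
per-solid-volume capacities) will disagree with this package mainly in
front positions and cut times; the ledgered acceptance analysis quantifies
this for the shipped reference values.

## Core–shell radial transform

The shell coordinate is replaced by the cumulative shell-volume fraction

```
Ω(ϑ) = (ϑ³ − ϑ_core³) / (1 − ϑ_core³) ∈ [0, 1]
```

so uniform Ω cells are exact equal-volume shells and the cell averages of a
finite-volume scheme are true volume averages.  The diffusion operator
transforms to `η β² ∂/∂Ω (ϑ(Ω)⁴ ∂c/∂Ω)` with `β = 3/(1−ϑ_core³)`; the
surface flux becomes `η β Bi (c_b − c_p|Ω=1)`.  At `ϑ_core = 0` the map
degenerates smoothly to `Ω = ϑ³` for fully porous beads; a test verifies the
fully porous limit against an independent uniform-`ϑ` spherical
discretization integrated with a stiff ODE solver (outlet curves agree to
0.5% of peak height with matched bulk discretizations).

## Spatial discretization

Cell-centered finite volumes on a uniform `N_x × N_Ω` mesh (default
100 × 80).  Advective face values are reconstructed upwind; at second order
the Koren-type flux limiter

```
Σ(r) = max(0, min(2r, (1+2r)/3, 2)),   r = (upwind Δ + Γ)/(local Δ + Γ)
```

limits the reconstruction (`Γ = 1e−10` guards vanishing denominators; a van
Leer limiter `Π(r) = (r+|r|)/(1+|r|)` is provided as an alternative).
Boundary faces always use the first-order backward value.  Axial dispersion
is discretized with central face gradients, the radial operator in
conservative flux form with central face gradients — no radial limiter is
needed because the radial equation is purely diffusive.  The surface value
`c_p|Ω=1` is closed to second order from the outermost cell and the Robin
condition, and the same closure feeds the bulk sink, which makes the
bulk–particle exchange exactly conservative cell by cell.

The per-cell accumulation matrix `A = ε_p I + ∂q*/∂c` (analytic bi-Langmuir
Jacobian, components coupled) multiplies the particle time derivative and is
inverted cell by cell.  Pore concentrations are clipped at zero for isotherm
evaluation only; clips beyond −1e−10 are counted and reported in the run
manifest, never silently applied to the state.

## Time integration

Two modes share the spatial scheme:

* **`imex` (production default).**  The bulk convection–dispersion fluxes
  advance with the two-stage TVD Runge–Kutta (Heun) scheme; intraparticle
  diffusion and film exchange — whose explicit stable step would be
  `~ε_p ΔΩ²/(2ηβ²)`, i.e. 1e−6 and smaller on fine shell grids — are
  advanced by L-stable backward-Euler stages embedded in the same two
  stages.  Each implicit stage solves, per axial cell, a block-tridiagonal
  Newton system in the conservative variable `ε_p c + q*` (two iterations
  sharing one factorization), which keeps the adsorbed phase in the global
  mass balance: the injected pulse is recovered at the outlet to better
  than 0.5% on the default grid.  The step size is fixed per run from the
  convective and axial-dispersion limits (`Δξ = safety / (1/Δx +
  2/(Pe Δx²))`, default safety 0.5) and snapped to divide the output
  sampling interval.
* **`explicit`.**  Plain two-stage TVD-RK2 on the complete semidiscrete
  system under the full harmonic-sum CFL bound (convection, axial
  dispersion, radial diffusion, film relaxation; the accumulation floor is
  `ε_p`).  Practical on coarse shell grids only; it is the reference
  implementation the IMEX path is validated against (outlet curves agree to
  0.3% of peak on shared grids).

Both modes are strictly deterministic: reruns are bit-identical, and every
run writes a manifest sufficient to reproduce it exactly.

## Fractionation metrics

For a target solute (default: the first-eluting component) with detection
threshold 1% of its own `c_inj`:

* `ξ¹` — target first exceeds its threshold at the outlet; collection starts;
* `ξ²` — the last component falls below its threshold for good;
* cycle time `ξ_cyc = ξ² − ξ¹` — the re-injection interval;
* cut time `ξ_cut` — collection stop such that the collected fraction's
  peak-area purity equals the required level (default 99%), found by a
  bracketed, deterministic root search on the cumulative trapezoidal areas
  (resolved well below one output sample); for non-overlapping bands the
  cut is the end of the target peak;
* recovery yield `Y = m₁/(c_inj ξ_inj)` with `m₁` the collected amount;
* reduced productivity `Y^Pr = c_inj · m₁ / ξ_cyc`.  The extra `c_inj`
  factor (relative to a naive amount-per-cycle-time) matches the tabulated
  convention of the reference study this implementation reproduces, and is
  internally consistent with its yield and cycle-time columns to ≤0.5%.

Metric integrals use the chromatogram's uniform sample grid (default
spacing 0.05; the reference-scenario analyses sample at 0.02 because the
high-core-fraction metrics are order-one numbers needing finer quadrature).

## Scenario library and generator

The shipped scenarios carry the reference parameter set (`Pe = 1500`,
`Bi = 50`, `η = 2.0`, `ε_b = 0.4`, `ε_p = 0.5`, `c_inj = 1`, `ξ_inj = 1`;
site constants `(10,15,0.5,1.0)`, `(30,35,1.5,2.0)`, `(70,75,3.0,3.5)`).
`random_scenario(seed)` draws reproducible configurations in physically
sensible ranges (`Pe ∈ [100,3000]`, `Bi ∈ [1,200]`, `η ∈ [0.1,5]`,
`b ∈ [0,10]`, `ϑ_core ∈ [0,0.9]`) for property tests.  The default
simulation window is sized from the slowest linear-limit retention time
(`1.3 ξ_R + ξ_inj + 5`); kinetic tailing at slow intraparticle rates can
extend beyond the 1%-threshold crossing, so mass-balance studies use longer
windows explicitly.

These scenarios exercise idealized columns: uniform beads, constant
porosities, concentration-independent transport coefficients and a clean
rectangular pulse.  Passing tests demonstrate the solver reproduces the
model's mathematics (conservation, convergence order, limits and
cross-discretization agreement); they do not validate the GRM against
measured chromatograms of a real packed column.

## Numerical choices and limitations

* Fixed step per run; stability is re-checked by construction (the stiff
  part is unconditionally stable, the explicit part convection-limited).
* The modified-Newton stage solve converges linearly; two iterations leave
  stage residuals far below the spatial truncation error at production
  steps (a test drives the residual to 1e−10 with extra iterations).
* Compiled kernels use fastmath; results are bit-identical between runs of
  the same build (the determinism the tests assert), though not guaranteed
  identical across compiler versions.
* Outlet samples are whole accepted steps (no interpolation); tiny negative
  outlet values are clipped to zero at sampling only.
* Degenerate inputs rejected with named-field errors: porosities outside
  (0,1), core consuming the whole bead, nonpositive transport coefficients,
  empty component lists, unattainable purity (co-eluting bands) and
  incomplete elution windows raise instead of returning garbage.
* Not covered by design: temperature effects, pH/salt-modulated or
  steric-mass-action isotherms, surface diffusion, radial column gradients,
  adaptive meshing, implicit/IMEX alternatives beyond the scheme described,
  multi-column (SMB) operation, isotherm fitting to data.
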