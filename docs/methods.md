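# Methods

`poromcts` simulates a multicellular tumor spheroid (MCTS) as a
reactive porous multiphase continuum, either growing freely in culture
medium or confined inside an elastic alginate microcapsule whose
dilation acts as a pressure sensor (Cellular Capsule Technology, CCT).
This note records the model, the numerical scheme, the default
parameters and the reasoning behind every choice the design left open.

## The multiphase model

Three phases share each representative volume: an extracellular-matrix
solid scaffold `s` with volume fraction `1 − ε` (ε is the porosity), a
tumor-cell phase `t` and the interstitial fluid `l`, with saturations
`S_t + S_l = 1` of the pore space.  All phases are incompressible
(constant densities, Biot coefficient 1).  Primary unknowns are the
radial scaffold displacement `u_s`, the IF pressure `p_l`, the
cell/IF pressure difference `p_tl = p_t − p_l` and the oxygen mass
fraction `ω` dissolved in the IF; internal variables are the porosity
ε and the necrotic mass fraction `ω_Nt` of the cell phase.

Closure laws:

* **Pressure–saturation.** `S_t = (2/π) arctan(p_tl / ((1 − ω_Nt) a))`
  with `a` the ECM-thinness / cell-surface-tension parameter (Pa).
  The necrotic offset makes dead, collapsed regions denser at equal
  pressure difference.  For `p_tl ≤ 0` the saturation is clamped to
  zero: there is no cell phase where cell pressure does not exceed IF
  pressure (the exterior medium).  The written form of the necrotic
  offset is ambiguous in its source; we place `(1 − ω_Nt)` in the
  denominator so that increasing necrosis increases saturation.
* **Mechanics.** Biot effective stress `σ' = σ + p_s I` with the solid
  pressure `p_s = S_t p_t + S_l p_l`; linear-elastic effective stress
  with per-subdomain `(E, ν)`.
* **Transport.** Darcy flow of both fluid phases with relative
  permeability `S_f^A` (A = 2 for both by default; the exponents are
  not constrained by the data and are exposed as configuration);
  Fick diffusion of oxygen with tortuosity, `D = D0 (ε S_l)^2`.
* **Biology.** Growth transfers mass from IF to cells at rate
  `γ_gt · H(ω) · (1 − Hp(p_t)) · (1 − ω_Nt) ε S_t`, where `H` is a
  cosine ramp between the hypoxia threshold `ω_crit` and the optimal
  oxygenation `ω_env`, and `Hp` a linear ramp between the inhibition
  onset `p1` and the full-stop pressure `p_crit`.  Oxygen is consumed
  by a growth-linked term and a basal metabolic term (scaled by the
  metabolic ramp `H̃`); hypoxic necrosis converts living to dead cell
  mass at rate `γ_Nt (1 − H̃)`.

### Unit convention for the necrosis coefficient

All biological rate coefficients (`γ_gt`, `γ_gnl`, `γ_0nl`, `γ_Nt`)
carry kg/(m³·s); the necrosis source in the necrotic-fraction balance
is `γ_Nt (1 − H̃)(1 − ω_Nt) ε S_t` in mass units, so the specific
necrosis rate is `γ_Nt / ρ_t = 1e-5 s⁻¹` at the default
`γ_Nt = 0.01 kg/(m³ s)`.  Reading `γ_Nt = 0.01` as s⁻¹ instead would
necrose any mildly sub-optimally oxygenated tissue within minutes,
which is inconsistent with necrotic cores that develop over days and
with viable rims persisting ~85 h after confluence; the mass-rate
reading keeps the coefficient dimensionally uniform with the other
three rates.

## Three spatial subdomains

The 1-D radial domain `[0, R_domain]` holds up to three concentric
material regions: the intracapsular tissue region (ECM scaffold,
E = 1 kPa), the alginate shell (E = E_alg, 68 kPa by default) and the
exterior medium.  The poroelastic framework requires a solid fraction
everywhere, so the exterior carries a mechanically negligible
fictitious scaffold (E = 0.6 kPa, porosity 0.99).

The cell phase exists only where the physics allows it: never inside
the alginate gel, whose ~20 nm pores exclude cells.  This is enforced
structurally — the saturation law is masked to zero on shell elements —
rather than through a permeability penalty alone, because the growth
source is autocatalytic: any spurious discrete saturation inside the
shell would be amplified exponentially regardless of how small the
cell-phase permeability is made.  (A cell-phase permeability penalty,
`k_cell_factor = 1e-6` in the shell, is kept as well.)  In free
growth the spheroid advances into the exterior medium, which is
therefore cell-capable.

## Discretization

Fields depend on the radius only (spherical symmetry); displacement is
purely radial.  Mixed continuous Lagrange elements: displacement one
polynomial order above the scalars (default P2/P1), nodes placed
exactly on subdomain interfaces.  Time stepping is implicit Euler
(base `dt = 1200 s`) with an incremental updated-Lagrangian geometry
update: after each converged step the vertex coordinates move by the
displacement increment, strains and porosity accumulate
(`(1 − ε) J` conserved pointwise for incompressible grains), and the
necrotic fraction advances by a pointwise backward-Euler update solved
in closed form (its balance is quadratic in the new value).  The
necrotic fraction is treated as a material internal variable without
its own advection term.

Numerical choices that matter:

* **Lumped storage.**  Flux, momentum and stiffness terms use Gauss
  quadrature; storage and reaction terms are mass-lumped at the
  element-local nodes (row-sum lumping including the `r²` metric).
  With a consistent mass matrix the Newton iteration develops limit
  cycles at the degenerate saturation front (the node just ahead of
  the front is driven to large negative `p_tl` and snaps back);
  lumping removes the cross-node storage coupling and restores
  monotone convergence.  The single-fluid consolidation mode uses the
  consistent form (no front exists there, and lumping would only cost
  accuracy against the analytic benchmark).
* **Smoothed clamp.**  Inside the solver the saturation clamp at
  `p_tl = 0` is rounded by a softplus of width `1e-4·a` (≈0.1 Pa) so
  the Jacobian stays continuous at the cell front.  Source terms use
  the exact clamped law: the smoothing floor (S_t ≈ 4e-5 at
  `p_tl = 0`) must never seed the autocatalytic growth term in
  cell-free regions.
* **Storage regularization.**  Where the cell phase is absent the
  cell-mass equation is degenerate (zero storage derivative, zero
  mobility).  A storage regularization of relative size `1e-6` of the
  saturation capacity freezes `p_tl` at its previous value there.
  Its mass defect is charged to the reported mass budget (the raw
  residual used for budgets excludes the regularization term), and the
  per-step budget stays below 1e-6 of total mass in all shipped
  configurations.
* **Jacobian.**  Finite differences on the residual with a greedy
  coloring of the element-connectivity graph (columns conflict when
  they share or neighbor an element; ~15 colors), so all pointwise
  closures — switches, saturation, the implicit necrosis update — are
  differentiated consistently.  A modified-Newton strategy reuses the
  factorization while the iteration contracts strongly and rebuilds
  it otherwise; a backtracking line search on the scaled Newton-step
  norm guards each iteration.  On Newton failure the time step is
  halved (down to `dt/2^6`) and later re-doubled.
* **Mass budgets.**  Because the Lagrange basis is a partition of
  unity, summing the unconstrained residual rows of a mass balance
  over the free dofs yields exactly the discrete budget
  "storage change − sources + consistent boundary flux".  This is the
  per-step conservation defect reported in the time series.
* **Confluence detection.**  The front radius is the outermost radius
  where the nodal saturation reaches half its maximum, with the nodal
  projection taken one-sided (element-local maximum) so the
  tissue/shell interface node carries the tissue-side value;
  confluence is the (linearly interpolated) time this radius reaches
  the current inner wall radius.
* **Wall quantities** are averaged over the outermost two tissue
  elements inside the capsule wall; reported strain is
  `u(R_in)/R_in0`.

## Default parameters

Cell-line parameters follow the two shipped presets (`generic` and
`CT26-optimized`); `μ_t = 36 Pa·s` and `γ_gnl = 4e-4 kg/(m³ s)` keep
their generic values in the optimized preset ("not identifiable from
the data", not zero).  `ω_env = 4.2e-6` (~90 mmHg) is both the
physiological optimum and the far-field Dirichlet value;
`ω_crit = 1e-6` (~20 mmHg).

Transport and material constants that no experiment in this setting
pins down are set once to literature-scale values and exposed in
configuration:

| constant | default | rationale |
| --- | --- | --- |
| ρ (all phases) | 1000 kg/m³ | aqueous tissue |
| μ_l | 1e-3 Pa·s | water / culture medium |
| D0 | 3.2e-9 m²/s | oxygen in water |
| k | 1e-16 m² | see below |
| ε0 | 0.8 (tissue), 0.99 (exterior) | dense cellular aggregate |
| ν | 0.4 everywhere | nearly incompressible soft matter |

The intrinsic permeability `k` controls how dense the advancing cell
rim is (mobility `k S_t²/μ_t` against the growth rate).  It was chosen
once, against two stated experimental facts: the MCTS at confluence
consists of ~40% interstitial fluid (wall saturation ≈ 0.6), and
confluence of the reference capsule occurs between day 1 and 2.
`k = 1e-16 m²` reproduces both (wall S_t ≈ 0.56, confluence ≈ 1.7 d);
an order of magnitude higher makes the rim arrive far too dilute.
The initial seed is a 50 µm sphere at saturation 0.6 (the confluence
composition), smoothed over 10 µm.

## What the synthetic generator does and does not emulate

`generate_synthetic_experiment` runs the forward model at known
parameters and samples either the free-growth volume at day marks or
the capsule outer radius, adding multiplicative Gaussian noise
(default 2%, seeded).  It reproduces the *structure* of the
experimental curves — monotone volume growth, strain that rises after
confluence and saturates — but not their biological variability:
real aggregates differ in initial size, shape and cell-line state, and
real capsules have heterogeneous stiffness and thickness.  Passing
parameter-recovery tests on such surrogates therefore demonstrates
identifiability of the inverse problem under the model's own physics,
not accuracy against laboratory data.

## Sensitivity and calibration

The sensitivity procedure is the *local* response-surface variant:
one-at-a-time perturbations on a [−10, −5, −2, −1, +1, +2, +5, +10]%
grid, relative cost variations fitted by a linear (first-order) or
quadratic (pairwise) polynomial in the normalized perturbations, and
Sobol-type indices from squared coefficients (they sum to one by
construction).  It is not a global Saltelli estimate.  Two cost
functions mirror the two configurations: summed squared volume
mismatches at days 1–4 (free), and the inner-wall displacement
mismatch plus squared solid-pressure mismatch one day after confluence
(confined).  The displacement term uses the absolute value by default
(a `squared` dialect is available); in the 1-D spherical reduction
boundary averages are the wall values themselves, which resolves the
unit mixing of the two terms trivially.

Calibration is bounded Nelder-Mead (scipy) on the x/x0 scale from a
small multi-start spread, in two stages: (γ_gt, γ_0nl, a) on free
data, then (p1, p_crit) on confined data with the stage-1 values
frozen; candidates with `p1 ≥ p_crit` are rejected before the forward
model runs.

## Problem sizes used by the shipped checks

The acceptance script runs the consolidation benchmark at
dh = 5 µm / dt̄ = 1e-4 (20 elements, 10⁴ steps), the mesh-degradation
pair at dh = 5 and 2.5 µm over four days, and the reference capsule at
dh = 5 µm / dt = 1200 s to confluence + 85 h.  Test-suite pipelines
that need many forward runs (sensitivity designs, recovery) use
coarser desk-scale settings, dh = 25 µm / dt = 4800 s for free growth
and dh = 10 µm / dt = 4800 s for capsules; the reported sensitivity
rankings are stable at these resolutions.

## Known limitations

* The 1-D spherical reduction cannot represent non-spherical modes
  (capsule ovalization, asymmetric seeding).
* Small-strain increments on an updated geometry; shell strains of
  15–20% (thin capsules) stretch that assumption, and the inverse
  shell formulas assume incompressible alginate while the forward
  model uses ν = 0.4.
* In the reference capsule run the IF pressure excursion grows to a
  few tens of Pa late after confluence, when the nearly saturated
  necrotic core (S_l → 0.01) chokes IF mobility; reported reference
  behavior for this quantity is a few Pa.  The sign structure
  (suction ahead of the front, positive core pressure after
  reversal) is reproduced.
* Free-growth simulations fill the default 300 µm domain after about
  a week; longer horizons need a larger `R_domain`.
* Identifiability: free-growth volume data constrain the growth rate
  strongly but the saturation parameter `a` only weakly (its local
  variance share is a few percent), so two-stage identification
  carries a residual `a` bias of up to ~8% into stage 2, where the
  inhibition-onset threshold `p1` — itself the weakest-identified
  parameter — absorbs it and can end 20–25% off even on noise-free
  synthetic data.  The full-inhibition threshold `p_crit` is robust
  (within a few percent).
* No nutrient species beyond oxygen; no stress-induced phenotype
  switching; no contact mechanics beyond the continuum fields.
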