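# Methods

## The model

`tumormg` simulates multispecies desmoplastic tumor growth in a tissue
domain Ω ⊂ ℝ³ (a 2D mode exists for fast experimentation) as a
thermodynamic mixture with a diffuse-interface description of the cell and
matrix phases. The solid phase is partitioned into normalized volume
fractions of viable tumor cells φ_V, dead tumor cells φ_D, extracellular
matrix (ECM) φ_E, and healthy host cells φ_H = 1 − φ_V − φ_D − φ_E (the
identity holds cell-wise at all times because φ_H is derived, never
evolved). The fractions obey advection–diffusion–reaction equations

  ∂φ_i/∂t + ∇·(φ_i u_α) = ∇·(M_i ∇μ) + S_i,

where the chemical potentials μ_T (tumor) and μ_E (ECM) are variational
derivatives of a Helmholtz free energy with a ternary bulk part F_b,
square-gradient interface terms (coefficients ε_T, ε_E and a cross term
ε_TE), and an optional ECM elastic energy W with dilatational eigenstrains
and Q3-interpolated Lamé moduli. The mixture velocity u_α is a Darcy flow
driven by the cell–ECM pressure p, which solves a variable-coefficient
elliptic equation forced by the net source −(S_V+S_D+S_E); the ECM phase
additionally drifts down its own potential gradient (u_E = u_α − M̃∇μ_E,
M̃ = M̄φ_E).

Diffusible species — oxygen n, glucose g, CO₂ w, the ions
lactate/bicarbonate/H⁺/Na⁺ with Cl⁻ closed by electroneutrality, tumor
growth factor tgf, and angiogenic factor taf — are quasi-steady
reaction–diffusion fields re-equilibrated every step. Their diffusivities
and vascular mass-transfer coefficients are tissue-effective blends
ψ = ψ_E Q3(φ_E) + (1−Q3(φ_E))[ψ_T Q3(φ_T/φ_C) + ψ_H(1−Q3(φ_T/φ_C))] with
φ_C = φ_T + φ_H. Matrix-degrading enzymes m, ECM-based myofibroblasts F_E,
and continuum blood/lymphatic vessel densities B_nE, L_nE are transient:
they advect with u_E, chemotax up tgf/taf gradients and haptotax up ∇φ_E,
and (for m and the vessels) diffuse.

Source terms gate mitosis on oxygen above a hypoxic level n_h = 0.3
(upregulated by tgf), switch viable cells to necrosis below the viability
limits (n < 0.21 or g < 0.1), lyse dead cells at unit rate, and balance
myofibroblast-driven ECM secretion (rate 5, gated on tgf > 0.2 and on free
host volume, hypoxia-upregulated by a factor up to 1 + F_n,EF = 3) against
MDE-driven degradation (rate 5).

## Discretization and solver

Space is discretized on a block-structured cell-centered Cartesian
hierarchy: global levels κ_min..0 each cover Ω with one block and spacing
halving per level; refinement levels κ ≥ 1 are unions of rectangular
blocks properly nested in the level below, each block carrying one ghost
layer per face. Interior cells are indexed 1..N with ghosts 0 and N+1;
cell centers sit at L + (i−1/2)η.

Time stepping is Crank–Nicolson with a fixed step θ. The fourth-order
Cahn–Hilliard equations are split into second-order pairs: the five fields
(φ_V, φ_D, φ_E, μ_T, μ_E) are solved simultaneously per step. Mobilities
M_i = M̄φ_i are frozen at the old time level; advection (first-order
upwind on face velocities), all source terms, the elastic derivative, and
the surface-adhesion cross terms ε_TE²∇²φ are treated explicitly at the
old time. The explicit pieces make the overall scheme first-order accurate
in the joint space–time refinement limit even though the core
discretization is second order — this is deliberate and is what the
convergence study measures.

Each step's nonlinear system L(ψ) = R is solved by an adaptive Full
Approximation Scheme (FAS) full multigrid iteration:

* **Transfer operators.** Restriction is 2³-child averaging; correction
  prolongation is trilinear (tensor-product weights 3/4, 1/4, i.e. the
  {27,9,3,1}/64 child stencils); the FMG initial guess and newly refined
  blocks use tensor-product cubic Lagrange interpolation with 1D weights
  (−7,105,35,−5)/128. Coarse–fine ghost cells are filled by a two-stage
  quadratic interpolation: a tangential pass with weights (30,5,−3)/32 per
  tangential axis onto intermediate points, then a normal quadratic
  through the intermediate value and two interior fine cells (weights
  8/15, 10/15, −3/15); edge and corner ghosts interpolate along the inward
  diagonal. Ghosts overlapping a same-level neighbor's interior are then
  replaced by that neighbor's cell values, and physical boundaries use the
  second-order cell-centered conventions (mirror for no-flux, 2v−interior
  for Dirichlet). Where a wide stencil would leave the available data
  (only near physical corners), missing values are filled with the nearest
  data; the order reduction is local to the outermost cells.
* **Smoother.** Nonlinear red–black Gauss–Seidel: cells are colored by the
  parity of the global index sum; for each cell of a color the 5×5
  diagonal block (the local equations with neighbors frozen) is solved by
  at most 5 Newton steps on the batched Jacobians, with a linearized
  Picard fallback if a Newton update is non-finite. ν_b extra sweeps are
  applied to cells within d_κ of block boundaries (d_κ = 2^{κ−κ_min} on
  global levels, min-block-dimension/8 on refined levels). Ghosts are
  refreshed between sweeps. The supplementary pointwise relaxation formula
  of the original solver is not public; this collective Newton relaxation
  is our reconstruction of it and is validated against loop-level and
  dense two-grid oracles.
* **Cycles.** The adaptive V-cycle (γ=1; W-cycle plumbing via γ=2)
  restricts the iterate onto the coarse overlap, builds the τ-corrected
  coarse right-hand side R[R_κ − L_κψ] + L_{κ−1}(Rψ) there (the coarse
  level keeps its own RHS elsewhere), recurses (ν₀ smoothing at the
  coarsest level), and prolongs the coarse correction ψ̄ − ψ⁰. Coarse-grid
  operators are re-discretizations on the coarse grid, not Galerkin
  products.
* **FMG.** Each step starts from the previous solution, smooths the
  coarsest level, performs r_κ cycles per level below the root, and on
  levels κ ≥ 0 cycles until ‖R − L(ψ)‖ (scaled discrete l₂ norm over
  level interiors) falls below tol_κ = tol_min·σ^{κmax−κ}; the minimum
  tolerance sits on the finest level because the schedule tightens with
  refinement. After a level converges, the refinement criterion may grow
  the hierarchy by one level, with cubic interpolation seeding the new
  level's iterate.
* **Adaptivity.** Cells are flagged by the undivided gradient test on the
  total tumor fraction φ_T (the flagged quantity is configurable): the sum
  of squared undivided centered differences is compared against C_κ as a
  first power — not C_κ² — matching the printed criterion. A relative
  truncation-error test is available as the alternative criterion (off by
  default). Flags are buffered by 4 cells per direction (9³ cubes, clipped
  at external and block boundaries) and clustered by signature-based
  splitting (gap, then second-difference inflection, then midpoint
  bisection; empty edge slices trimmed; acceptance by efficiency ≥ 0.9,
  size ≤ 2×1000 cells, or efficiency ≥ 0.5). Ties for "closest to center"
  break toward the lower index and axes are scanned longest-first
  (x→y→z on ties). Regridding migrates current data by cubic
  interpolation from the coarse level, copies previous-time data where new
  cells overlap old ones, and averages vacated fine data down. During the
  in-step regrid the Cahn–Hilliard unknowns are *not* averaged down (the
  coarse level already holds the newer converged iterate); everything else
  is.

The pressure, the quasi-steady species, and the implicit halves of the
m/B_nE/L_nE updates reuse the same multigrid machinery with a linear
scalar smoother; the charged-species block is Picard-iterated around the
shared electro-diffusive drift (denominator floored at 1e−12 so
tumor-free regions cannot divide by zero). The elasticity system
∇·𝕋 = 0 is solved matrix-free (GMRES) on the root level with a
conservative face-flux discretization and zero-displacement boundaries.

## Default parameters

Solver defaults follow the reference configuration: γ=1, ν₀=4, ν₁=ν₂=2,
ν_b=2, r_κ=1, σ=4, minimum tolerance 5×10⁻⁴, θ=10⁻², C_κ=0.05 (one scalar
for all levels), threshold_eff=0.9, threshold_size=10³, min_eff=0.5,
buffer radius 4, outer-cycle cap 50 per level. The reference domain is
Ω=(0,40)³ with three global levels (8³, 16³, 32³ — η₀ = 40/32 = 1.25) and
up to two refinement levels (η₂ = 40/128).

Model constants printed in the main model description (necrosis/lysis/ECM
rates, viability thresholds, far fields B_∞ = L_∞ = 0.2, the seed
composition φ_V = 0.65 / φ_E = 0.35) are hard defaults. Everything that
lives in the unavailable supplementary tables is a documented order-one
placeholder, flagged as such in `tumormg/data/reference_config.yaml` and
fully configurable. The key choices, made once on physical grounds:

* **Bulk energy** A₁=1, A₂..A₅=0: the well of the ternary energy then sits
  at φ_T = 1−φ_E, so the seeded state (0.65, 0.35) is an energy minimum
  and the interface relaxes rather than drifts.
* **Interface widths** ε_T = ε_E = 1, ε_TE = 0.5 (dimensionless lengths in
  the 40-unit domain): the diffuse interface spans a few cells of the
  refined levels, which is what the refinement criterion is designed to
  capture; ε_TE < √(ε_T ε_E) keeps the cross-gradient energy subdominant,
  which matters because that term is explicit.
* **Mobility and motilities** M̄ = k_α = k_β = 1, γ_T = γ_E = 1.
* **Q3(φ) = φ²(3−2φ)** clamped to [0,1]: the standard smoothstep with the
  required endpoint values (the original interpolant is not printed).
* **Vascular supply** n_C = B_nE·φ_E (and likewise g_C, w_C, l_C): supply
  must vanish where there are no vessels. With the order-one uptake
  triples (tumor-weighted: (0.05, 1, 0.05)) the ambient oxygen settles
  well below the viability limit, so the seeded tumor necroses from the
  core and regresses over the simulated window — the qualitative regime of
  the reference scenario. Realistic vascular oxygenation would need the
  supplementary constants.
* **Sprouting-fraction map**: octant-constant values 0.1..0.8 (quadrants
  in 2D), a minimal realization of the "different fractions in different
  regions" symmetry perturbation.
* **Elasticity off by default** (ε_e = 0) since Lamé moduli and
  eigenstrains are supplement-only; the implementation (including the
  printed stress-jump form with its (1−L_2C) coefficient, which reduces
  to the usual jump when L_2E = 1) is exercised by tests.
* **μ_H** appears only in the boundary conditions and has no evolution
  equation; it is not carried. The unspecified mobility in u_E defaults to
  M̃ = M̄φ_E.

The reduced **lite profile** evolves φ_V, φ_D, φ_E, the potentials, p, n,
g, tgf, taf, m, F_E, and both vessel densities; the ion block, the
interstitial pressure q, and elasticity are enabled by the full profile.
taf is kept in the lite profile because the vessel fluxes need its
gradient.

## Convergence study

The study follows the linear refinement path θ = 0.032·η_{κmax} at root
resolutions in ratio 2 (defaults 8³/16³/32³ with κ_max = 1, end time 1.0,
lite profile — sizes chosen so the full study runs in minutes on one
core). Where 0.032·η does not divide the end time, θ is adjusted to
end_time/round(end_time/θ) so every run ends at the same instant; the
deviation from the path is under 5% and affects only the coarsest run.
Each run's φ_T is composited onto its uniform η_{κmax} grid (coarse data
linearly interpolated upward, actual fine-block data overwriting it), the
finer run is averaged down to the coarser grid, and the convergence rate
is log₂ of the ratio of successive scaled-l₂ differences. The explicit
source/advection/adhesion terms dominate the error along θ ∝ η, so the
measured rate is ≈ 1 (first order), not 2.

## What the synthetic problems do and do not show

The manufactured fixtures (3D Poisson with a product-of-sines solution,
a scalar heat step, conservative scalar Cahn–Hilliard) validate the
multigrid machinery: mesh-independent V-cycle counts, O(η²) FMG error,
bit-level agreement of the adaptive two-level cycle with a dense two-grid
FAS oracle, and exact mass conservation of the divergence-form update
under no-flux boundaries. The tumor runs validate the coupled machinery
under the study conditions above. None of this certifies the biological
parameterization: with placeholder constants the simulated tumor's
quantitative trajectory (growth/regression rates, species profiles) is
illustrative, not predictive. The plain Crank–Nicolson step is only
conditionally stable for Cahn–Hilliard dynamics: θ must resolve the
interfacial time scale (the scalar fixture uses θ = 10⁻³ at ε = 0.1 for
this reason; the tumor defaults are comfortably inside the stable regime).

## Numerical details worth knowing

* Ghost corners at Dirichlet boundaries are filled by sequential slab
  reflection, which realizes the double odd reflection; the transfer
  operators consume these corner values, so oracle implementations must
  use the same convention.
* The clustering always terminates: every split strictly reduces block
  volume, and any single-cell box has efficiency 1.
* `count_dof` sums interior cells over *all* levels (coarse cells under
  refined blocks included; ghosts and boundary cells excluded): the
  three-global-level reference hierarchy has 8³+16³+32³ = 37,376 DOF.
* Degenerate guards: φ_C = 0 reduces the effective-coefficient blend to
  its host value; the ion drift denominator is floored; Heavisides are
  sharp with H(0) = 1 and evaluated pointwise.
* The checkpoint stores every padded array bit-exactly; restarted runs
  reproduce uninterrupted ones bit-identically (the model has no random
  ingredients).

## Known limitations

Refinement ratio fixed at 2 with cubic cells; no conservative (refluxed)
coarse–fine coupling, so mass conservation across refinement interfaces is
approximate (exact on uniform hierarchies); single-rate time stepping; the
relative truncation-error flag is implemented but not the default; no
parallelism. Ion chemistry and elasticity run at small scales only and
carry placeholder constants throughout.
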