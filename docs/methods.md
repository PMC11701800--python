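# Methods

`moabsim` models the perfused culture chamber of a miniaturized optically
accessible bioreactor (MOAB): a 6 × 3 × 0.5 mm cavity whose floor carries a
2 × 8 array of two-photon-polymerized microscaffolds (500 × 500 × 40 μm,
pores 50 × 50 × 20 μm framed by elliptical beams of 4.9 μm vertical × 1.0 μm
lateral cross-section). The package answers one design question: which
syringe-pump flow rate exposes cells in the scaffold pores to dermal
interstitial-flow conditions — velocities of 0.1–5 μm/s, wall shear stresses
of 0.1–10 mPa — without letting oxygen anywhere fall toward hypoxia.

## Flow model

Perfusion is creeping flow: at the largest candidate rate (10 μL/min) the
channel Reynolds number ρ u h/μ is below 0.1, so inertia is dropped and the
steady Stokes equations are solved. The medium is approximated as water at
37 °C, μ = 6.9 × 10⁻⁴ Pa·s, ρ = 993 kg/m³. With this viscosity the
parallel-plate operating shear 6μQ/(wh²) evaluates to 0.46 mPa at 5 μL/min,
which is the flat-chamber reference value the device is characterized by.

Resolving 1 μm beams inside a 6 mm chamber is not a desk-scale computation,
so the model splits scales:

* **Chamber scale.** The scaffold array is a Brinkman block:
  0 = −∇p + μ∇²u − (μ/κ)u inside the array, plain Stokes outside. The
  permeability κ comes from the Jackson–James correlation for
  three-dimensional fibre webs, κ = (3r²/20φ)(−ln φ − 0.931), with φ the
  lattice solid fraction (≈ 0.009) and r the equal-area-circle radius of the
  beam ellipse (≈ 1.1 μm), giving κ ≈ 7.5 × 10⁻¹¹ m². A resolved
  pressure-drop measurement on the voxelized lattice gives ≈ 5 × 10⁻¹¹ m²,
  agreeing with the correlation well within its factor-of-few accuracy (a
  unit test enforces a factor-3 bound); the correlation value is used
  because it varies smoothly with the configurable beam geometry.
* **Pore scale.** Each probed pore is re-solved in a resolved unit cell:
  one 50 × 50 μm pore column, periodic laterally, spanning the full chamber
  height (the cage plus the free fluid up to the no-slip ceiling). Beams
  are voxelized at 2.5 μm: their 4.9 μm vertical extent is captured, their
  1 μm lateral width is inflated to one voxel (a warning and a metadata
  record accompany this). The cell is driven by a uniform body force and —
  creeping flow being linear — rescaled so its volume-averaged velocity
  equals the chamber solution's local depth-averaged (superficial) velocity
  at the probe's (x, y). The full-height column matters: a short cell
  closed by a symmetry lid misrepresents the overlying channel flow and
  overestimates the near-cage shear by roughly a factor of two.

The discretization is a staggered (MAC) finite-volume scheme on a
rectilinear grid: velocity components on faces, pressure in cells, the
saddle system solved by conjugate gradients on the pressure Schur
complement with the velocity blocks LU-factorized once (they decouple per
component). Continuity holds to the iteration tolerance (10⁻¹¹ relative by
default; in practice the per-cell divergence is at rounding level).
Boundary conditions: a fully developed rectangular-duct profile at the
inlet face (the inlet/outlet cylinders are not meshed — the flow is treated
as fully developed at the chamber entrance, and the probes sit many chamber
heights downstream), p = 0 with zero normal gradient at the outlet, no-slip
walls, and a y = 0 symmetry plane so only half the chamber is computed
(a full-model mode exists and is used by the mirror-symmetry test).

Wall shear stress follows τ_zx = μ ∂u_x/∂z, evaluated one-sided into the
fluid on horizontal solid surfaces (chamber floor, beam top faces);
velocities vary far more strongly along z than along y here, so the other
shear components are not reported.

## Probes and sampling modes

Velocities are probed at the centres of pores 1, 5 and 10 of
microstructures 1, 4 and 8 (counted from the inlet), at 10, 20 and 40 μm
height; shear is averaged along the beam segments of each probed pore's
outlet-side face at the same heights (10 μm maps to the floor-level framing
beams, 20 μm to the mid-plane rung, 40 μm to the top rung). Two velocity
sampling modes exist, because "the velocity at the 40 μm layer" is
ambiguous exactly where cells live:

* *point* — trilinear sample at the pore centre (at 40 μm this sits on the
  array's top interface, where the chamber model gives 8–12 μm/s at
  5 μL/min, dominated by the free stream above the cage);
* *near-surface* (the documented default for feasibility) — the maximum
  speed one pore-grid voxel (2.5 μm) above the framing beams, i.e. the
  fluid layer an adherent, ~10-μm-tall endothelial cell actually occupies.

Feasibility judges near-surface maxima at the top layer: ≈ 4.5 μm/s at
5 μL/min, doubling past the 5 μm/s window at 10 μL/min. The wall-shear
feasibility metric is the area-averaged floor τ_zx over the flat part of
the chamber — the quantity that coincides with the totally-flat-chamber
value (0.46 mPa at 5 μL/min) because the sparse array barely perturbs the
outer flow; at 1 μL/min it scales to 0.092 mPa and misses the 0.1 mPa
stimulation floor. These two metric choices are the package's documented
resolution of what the top-layer figures summarize.

## Oxygen transport

Steady advection–diffusion with D = 2 × 10⁻⁹ m²/s and inlet concentration
C₀ = 0.2 mol/m³ (Henry's law for medium under incubator atmosphere).
Consumption is Michaelis–Menten per cell, V_max = 4 × 10⁻¹⁷ mol/s and
K_m = 5.5 × 10⁻⁴ mol/m³: 32,000 cells are spread as a uniform volumetric
sink over the array block, 18,000 as a surface flux on the flat floor strip
beside the array (the strip's lateral extent is a documented default —
floor between the array edge and the side wall over the array's axial
span — since the seeded area is not dimensioned; it is config-overridable).
Because K_m ≪ C₀ the system sits deep in the zeroth-order regime: total
consumption ≈ n·V_max = 2.0 × 10⁻¹² mol/s, and the mixed-cup outlet
concentration obeys C₀ − n·V_max/Q (0.176 mol/m³ at 5 μL/min), which the
independent 1D plug-flow oracle integrates without the 3D solver.

Discretization: first-order upwind convection against the divergence-free
staggered fluxes plus two-point diffusion — an M-matrix, so concentrations
stay in [0, C₀] unconditionally. The saturating sink is handled by Picard
iteration with a lagged denominator, V_max/(K_m + C_old)·C implicit, which
preserves the M-matrix property; convergence (relative update < 10⁻⁸) takes
~10 iterations at the reference load. Upwinding costs accuracy, not
boundedness: the manufactured-solution study shows clean first-order
convergence, and the axial cell Péclet of ≈ 1.4 on the default grid smears
the profile slightly without moving the mass balance.

Concentrations convert to percent atmospheric O₂ linearly through the
anchor 0.2 mol/m³ ↔ 18.6 %. Reported "drops" along a line are, by default,
differences in percentage points on that scale (a 0.06 mol/m³ drop is
5.6 points, landing at 13 % — dermal normoxia); the relative-percent
reading is computed alongside. Hypoxia is flagged below 1 %. Line profiles
are taken at 10 μm height — the lowest-oxygen layer, and the height of
cells on the floor — along the scaffold-row centreline and along the
midline of the flat strip.

## Operating-point selection

For each candidate rate {1, 3, 5, 10} μL/min the pipeline computes the
three metrics and their flags; flow at the other rates is obtained from one
solve by linearity, oxygen is re-solved per rate (the kinetics are
nonlinear in Q). The recommendation rule is "largest feasible Q" — the
strongest mechanical stimulus still inside every physiological window —
configurable to smallest/midpoint. On the reference configuration 1 μL/min
fails the shear floor, 10 μL/min overshoots the velocity window, and
5 μL/min is recommended. An infeasible sweep returns an explicit
no-feasible-operating-point result rather than raising.

## Problem sizes and numerical defaults

The default chamber grid is 50 μm laterally (grid lines snapped onto the
scaffold footprint edges so the porous block is conforming and its volume
exact) with 5 μm vertical cells up to 50 μm and geometric coarsening above
(136 × 30 × 26 cells for the half chamber); the default pore cell is
2.5 μm (20 × 20 × 39 with the graded column). These sizes were chosen so
the full pipeline (flow + nesting + oxygen) completes in minutes on one
core while keeping the bottom 50 μm — where every probe and both line
profiles live — at full vertical resolution. The test suite additionally
uses a coarse tier (100 μm / 10 μm / 5 μm) for whole-pipeline property
tests; the feasibility flags are stable across both tiers, while
printed-value comparisons use the default tier. Solver tolerances:
pressure-Schur residual 10⁻¹¹ (relative), iteration cap 10 000, Picard
10⁻⁸ / 50 — all config-exposed.

## Verification

* Method of manufactured solutions: a divergence-free trigonometric Stokes
  field (observed order ≈ 2 in velocity and pressure) and a cosine
  advection–diffusion field (observed order ≈ 1 for upwind), both run over
  grid-refinement ladders in the test suite and via `moabsim verify`.
* Closed-form oracles: plane Poiseuille (profile, floor shear), the
  Fourier-series rectangular duct (flux-normalized against independent
  quadrature), the Darcy limit on a 1D porous column (exact to solver
  tolerance), and the zeroth-order oxygen mass balance / plug-flow
  reduction.
* Property tests: discrete continuity, Stokes linearity in Q, concentration
  boundedness and monotonicity in cell number, probe-set geometry, config
  round-trips, deterministic outputs, and schema validity over randomized
  configurations.

## What the synthetic data does and does not emulate

The generator reproduces the reference device geometry and operating
conditions and perturbs them within fabrication-plausible bounds (±20 % on
dimensions, ±50 % on kinetics). It does not emulate: cell bodies
obstructing pores (the simulated scaffolds are bare, as in the reference
computation), growth-factor transport, temporal transients (medium is
treated as at steady state), fibroblast metabolism (only the endothelial,
highest-demand consumption is modeled), or fabrication defects in the beam
lattice. Passing tests therefore validate the transport model of the empty,
idealized device, not the biology grown in it.

## Known limitations

* The Brinkman closure smears the cage into a continuum at chamber scale;
  pore-interior point velocities there are reliable only to the screening
  length √κ ≈ 9 μm, which is why pore-level quantities are re-computed in
  the resolved cell.
* The one-way nesting matches the local superficial velocity but not the
  full local velocity profile; beam-level shear is accurate to tens of
  percent, consistent with the wide acceptance band used for it.
* The voxelized beams are 2.5× too wide laterally (one-voxel inflation),
  slightly overestimating cage drag and beam shear area.
* First-order upwinding adds numerical diffusion along x; drop magnitudes
  are mass-balance-anchored, but profile shapes are smoothed.
* The inlet/outlet cylinders are not meshed; entry effects within roughly
  one chamber height of the ports are not represented.
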