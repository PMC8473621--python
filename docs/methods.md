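# Methods

`osteoseed` models the first hours after an osteochondral implant
surgery: bone marrow seeps from the surrounding trabecular bone into
the defect that holds a 3D-printed titanium lattice scaffold, carrying
bone mesenchymal stem cells (BMSCs) that attach to the beams and to the
defect walls.  The package couples a two-phase filling simulation with
Lagrangian cell transport and an impingement adhesion rule, and
separately implements the radiographic analysis used to score bone
ingrowth on such scaffolds.  This note records the models, the default
parameters and why they hold their values, the numerical choices, and
what the synthetic fixtures do and do not demonstrate.

## Geometry

The titanium layer is a truncated cone (8.0 mm top, 5.9 mm bottom
diameter) filled with a log-pile lattice: sublayers of parallel
cylindrical beams (0.5 mm diameter) whose orientation rotates 90°
between sublayers.  The in-plane beam spacing is `pore_pitch +
beam_diameter` = 1.5 mm, leaving the nominal 1 × 1 mm pore windows.
The published characterization of this scaffold fixes only the beam
diameter, pore size and a porosity of 78.6%; the sublayer count and
vertical pitch are not recoverable.  We chose 11 sublayers and scanned
the layer height once over 6.8–6.95 mm, freezing 6.9 mm (vertical pitch
0.627 mm), which yields a voxelized porosity of 78.56% at 0.05 mm
voxels.  The same reasoning fixes the reported surface area only up to
the unknown layout; `surface_area` (marching-cubes on the implicit
solid) is reported with its estimator tag but never asserted.

The defect is a slightly larger truncated cone (8.2 / 5.88 mm, depth
6.9 mm).  Marrow enters through its lateral and bottom faces — the
surrounding bone is the reservoir — while the dense PLA cap seals the
top except for a 0.1 mm annular rim gap that vents the displaced air.
Voxelization is point-membership at voxel centres: deterministic, and
convergent (successive spacing halvings at ≤ 0.05 mm move porosity by
well under one percentage point).

## Reduced-scale flow model

The acceptance-scale simulation runs on a planar mid-plane section of
the defect (64 × 96 cells) rather than in 3D or axisymmetric
coordinates.  The lattice is not axisymmetric — azimuthally averaging
it would smear beams into solid annular plates and seal off vertical
flow — so the section keeps each sublayer as a row of circular beam
cross-sections, staggered by half a spacing between sublayers to stand
in for the alternating beam orientation.  The section carries unit
depth; all "volumes" are areas × 1 m.

The two phases (marrow, air) share one velocity field on a staggered
MAC grid.  Marrow is a shear-thinning power-law fluid,
η = k γ̇^(n−1) H(T) with k = 0.017 Pa·s^n, n = 0.708, clamped to
[0.001, 0.01] Pa·s; H ≡ 1 (isothermal).  Note k exceeds the upper
clamp, so below the crossover shear rate (k/η_max)^(1/(1−n)) ≈ 6.15 1/s
the working viscosity sits at the ceiling; the constants are applied
exactly as stated rather than reconciled.  γ̇ is the standard second
invariant, γ̇ = √(½ D̄:D̄) with D̄ = ∇u + ∇uᵀ.  Mixture density and
viscosity are volume-fraction weighted; air is 1.2 kg/m³ and
1.8 × 10⁻⁵ Pa·s.

Each step: (1) hybrid central/upwind advection (central below cell
Péclet 2, upwind above — second-order where it matters, monotone where
it must be) plus gravity, explicit; (2) variable-viscosity diffusion,
explicit but subcycled to a Gershgorin stability bound, with harmonic
viscosity averaging at faces and corners so marrow/air and wall corners
do not create artificial stiffness; (3) variable-density pressure
projection — matrix-free preconditioned conjugate gradients with a
direct LU factorization (refreshed when convergence degrades) as
preconditioner, stopping when the post-correction divergence bound is
below half the tolerance (default 10⁻⁶ 1/s); closed benchmark domains
are solved directly with one pinned pressure cell; (4) donor-cell VOF
transport of the marrow fraction.  Donor-cell is deliberately diffusive
but provably bounded in [0, 1] under CFL with a divergence-free field
and exactly conservative — both properties are asserted every step in
tests, and the cumulative-flux audit closes to machine precision.
Compressive interface sharpening was rejected because it risks exactly
the boundedness property the tests pin down, and interface sharpness is
not a reported quantity.

Boundary conditions: no-slip, zero roughness on every wall and beam
(internal solid walls are imposed at half-cell accuracy); fixed normal
inflow (1 mm/s) on inlet faces while injection is active; zero-pressure
outlet on the vent, which is widened to at least one grid cell since
0.1 mm is sub-grid at this resolution.  Time steps adapt to the
advective CFL (limit 0.4, cap 2 ms).  The solver reproduces the Ghia et
al. (1982) Re = 100 lid-driven cavity centreline to within 0.5% of the
lid speed on a 64² grid, which exercises advection, diffusion and
projection together.

## Cells

BMSCs are non-rotating rigid spheres, 25 µm, 1000 kg/m³, surface
tension 0.03 N/m (the source's "N/s" is read as a units typo).  50,000
cells enter uniformly over the inlet faces during the 2.5 s fill
window, apportioned so cumulative counts follow
round(rate × elapsed) — the window closes on exactly 50,000.  Two
post-fill scenarios mirror the study design: `no_injection` closes the
inlet at 2.5 s; `continued_injection` (the default, the condition the
study concluded was the more realistic) keeps cells and marrow coming
at 1 mm/s.  Reduced-scale runs use 5,000 cells.

Transport is one-way coupled (the suspension is dilute): semi-implicit
integration of Stokes drag with the Schiller–Naumann finite-Reynolds
correction plus buoyant weight.  The drag relaxation time at defaults
is ≈ 3.5 µs, far below the flow time step — cells are near-tracers, and
the semi-implicit update is stable regardless.  Fluid velocity is
interpolated bilinearly from the staggered grid (exact for linear
fields, verified).

Impingement is detected against the analytic section geometry: an
event fires when a cell's centre comes within one radius of a beam
cross-section or a defect wall while approaching it.  The Weber number
We = ρ_p d v_n²/σ classifies the event: stick (We ≤ 5), rebound
(5 < We < 10, specular with restitution 0.9), spread (We ≥ 10, treated
as stick with a recorded footprint factor).  These thresholds come from
the droplet-impingement literature (the original cell-impingement
calibration is not published in a recoverable form) and are
config-exposed; at the defaults We ≈ 10⁻⁶, so cells adhere on first
contact and the thresholds are not load-bearing.  Scaffold beams absorb
cells only after the fill (t ≥ 2.5 s, before that contacts reflect
elastically); the defect's bone walls absorb for the whole run.  Each
attachment is logged with surface, radial band (five side-to-side
bands), sublayer and beam id; densities are reported as beam-averaged
mass and as mass per unit surface area.

At the reduced scale the expected qualitative pattern emerges: outer
radial bands accumulate more mass per beam than the middle band, and
the continued-injection scenario ends with a markedly higher
defect-wall density than the closed-inlet scenario.  These orderings —
not magnitudes — are what the acceptance tests assert, averaged over
three seeds.

## Radiograph quantification

The image analysis is intensity thresholding on 8-bit grayscale
radiographs: scaffold iff I > 250, bone iff 60 ≤ I < 180 (the displayed
rule's inclusive lower bound wins over the loose prose), everything
else background/soft tissue.  The image is divided into equal grids
(default 10 × 10; remainders go to the last row/column) and each grid
scored with P_b = S_bone / (S_all − S_s); pure-scaffold grids are
undefined and excluded from aggregates.  Row/column profiles (with
optional 5-group pooling) expose vertical and side-to-middle trends.
Bone–scaffold contact is the share of scaffold interface pixels
(scaffold pixels with ≥ 1 non-scaffold neighbour) that have ≥ 1 bone
neighbour, under 4- or 8-connectivity; both are always reported since
the convention behind published per-animal values is unstated.  The
denominator choice (interface pixels) is our definition — the source
does not define one — and is recorded in the report metadata.  The
8-connectivity score dominating the 4-connectivity score is asserted
on random-image ensembles; it is an empirical regularity of such
textures, not a theorem.

## Synthetic data

Synthetic radiographs project the lattice along one horizontal axis;
metal is rendered overexposed (past the 8-bit ceiling) so it stays
above the 250 threshold under noise, bone speckle at intensity 120,
background at 30.  Bone pixels are planted by rank-transforming
smoothed noise to a uniform field and selecting against the local
target fraction — base + radial gradient + vertical gradient, defaults
0.32 + 0.22ρ̂ − 0.04ẑ to emulate the observed more-at-the-edge,
slightly-less-at-the-top ingrowth — with the total trimmed to exactly
round(Σp).  Pre-noise ground truth is returned with the image, so
recovery is asserted exactly at zero noise and within one percentage
point at σ = 5.

What passing these tests shows: the thresholding, gridding and
connectivity machinery is correct against known truth, and is robust to
moderate additive noise.  What it does not show: performance on real
radiographs, whose intensity distributions are not three well-separated
levels — beam-hardening halos, printing defects (metal powder reading
as intermediate gray) and genuine partial-volume pixels all blur the
class boundaries in ways the generator deliberately does not model.
Likewise the flow fixtures (uniform, linear shear, settling column)
validate kinematics and particle dynamics against closed forms, not
marrow rheometry.

## Problem sizes and determinism

Default analysis sizes are chosen as desk-scale: porosity at 0.05 mm
voxels (≈ 3.5 M voxels, seconds), the trend runs at 64 × 96 cells with
5,000 cells for 5 simulated seconds, and the schedule audit on a 32 ×
48 section.  All randomness flows through explicit integer seeds
(injection placement, speckle, test ensembles); deterministic stages
reproduce byte-identical CSV outputs under a fixed seed, which the CLI
test asserts.

## Known limitations

* The mid-plane section is a 2D surrogate: it preserves the radial and
  vertical structure of the lattice but not 3D connectivity, so
  absolute attachment counts are not comparable to a 3D run — only
  orderings and trends are used.
* Donor-cell VOF smears the marrow/air front over a few cells; fill
  *timing* is reliable (mass is exact), front *shape* is not.
* No marrow–air surface tension in the momentum equation; the vent gap
  is widened to one grid cell; tangential no-slip on internal staircase
  walls is accurate to half a cell.
* Cell proliferation, migration, differentiation, particle–particle
  interaction and detachment under shear are out of scope — the model
  stops at first attachment, which is exactly the quantity the
  downstream osteogenesis comparison uses.
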