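# Methods

`emimech` simulates the mechanics of cardiomyocytes embedded in
extracellular matrix with the two materials meshed as distinct
subdomains, in the spirit of cell-based (EMI-type) tissue models: an
intracellular space Ω_i, an extracellular space Ω_e, and an explicit
membrane surface Γ between them.  This note records the model, the
numerical choices, and what the defaults mean.

## Continuum model

Displacements are Lagrangian, `F = I + grad(u)`.  Both subdomains are
incompressible hyperelastic continua with exponential invariant-based
strain energies of Holzapfel–Ogden type evaluated on the modified
isochoric Cauchy–Green tensor `C̄ = J^{-2/3} F_pᵀ F_p`:

* intracellular:
  `ψ_i = a_i/(2 b_i) (e^{b_i (I₁−3)} − 1) + a_if/(2 b_if) (e^{b_if ⟨I₄f−1⟩₊²} − 1)`
* extracellular (isotropic):
  `ψ_e = a_e/(2 b_e) (e^{b_e (I₁−3)} − 1)`

with `I₁ = tr C̄`, `I₄f = f₀·(C̄ f₀)`, and `⟨x⟩₊ = max(x, 0)` so the
fiber term resists extension only.  The fiber direction f₀ is the cell
long axis (+x); sheet s₀ = +y; normal n₀ = +z.  `b → 0` limits reduce
analytically to neo-Hookean-type terms (no division by b anywhere in the
implementation).

Contraction follows the active-strain decomposition `F = F_p F_a` with a
transversely isotropic, exactly volume-preserving active factor
`F_a = diag(1−γ, (1−γ)^{−1/2}, (1−γ)^{−1/2})` in the (f, s, n) frame.
The activation γ(t) is scalar, spatially uniform inside the cells and
zero in the matrix.  Incompressibility `J = 1` is imposed weakly through
a pressure Lagrange multiplier, giving the augmented energy
`ψ* = ψ + p (J − 1)`.

The default material parameters are the averaged fitted values
`a_i = 5.70 kPa, b_i = 11.67, a_if = 19.83 kPa, b_if = 24.72,
a_e = 1.52 kPa, b_e = 16.31`.

### Activation transient

The default transient is parametric: a `sin²` rise from 0 to
`gamma_max = 0.2` at `t_peak = 138 ms`, then a `cos²` relaxation to zero
at `t_end = 500 ms` (half a cycle).  Tabulated transients (two-column
CSV) may be supplied instead.  Because the problem is quasi-static and
hyperelastic, any state of a contraction run depends only on the current
γ, not on the path; the continuation step count is a runtime knob only.

A caution on `gamma_max`: the reference experiments this model emulates
describe "contraction to a peak of approximately 20 % shortening" without
publishing the transient.  In this implementation γ = 0.2 produces a peak
*observed* mean fiber shortening of only ≈ 16 % (the matrix is soft, so
the cell shortens most of γ but stores little elastic fiber stretch), and
the averaged peak fiber stresses are correspondingly moderate
(≈ ±3 kPa).  The stress–activation curve is exponentially steep
(`b_if ≈ 25`): raising the activation peak to γ ≈ 0.26 — where observed
shortening is ≈ 20 % — raises peak σ_ff to ≈ ±8 kPa.  If "20 %
shortening" denotes the observed strain rather than the active strain,
the transient peak should be set near 0.26; the package keeps 0.2 as the
conservative literal default and exposes `gamma_max`.

## Geometry and meshing

A cell is an 18 μm-diameter cylinder of total length 102 μm (100 μm body
plus one 1 μm connection stub per end), blended into a flat connection
disk through a partial torus fillet: a circular arc of radius
11.1200 μm tangent to the cylinder, spanning an axial extent of 0.8
radii, meeting the disk (radius 4.552 μm) at slope 4/3.  The arc radius
was calibrated once, against the printed intracellular volume
24.42·10³ μm³, via the closed-form profile integral, and frozen.  A full
quarter-circle fillet would meet the disk vertically and badly shear the
structured extrusion below.  Matrix padding is 1 μm in the sheet
direction and 3 μm in the normal direction (a perimysium-like layer), so
the single-cell box is 102 × 20 × 24 μm.

Meshing is structured: the (y, z) cross-section is a triangle fan plus
concentric rings — rings inside the membrane scale with the axial radius
profile r(x), rings outside blend from the membrane circle to the box
rectangle — extruded along x with stations clustered at the stub and
shoulder.  Ring radii are inflated by the inverse square root of the
polygon area factor so the polygonal cross-section has exactly the area
π r(x)² at every station; discrete subdomain volumes then track the
analytic profile volume to a fraction of a percent at any resolution
(the builder enforces 2 %).  Prisms split into three tetrahedra using a
node-key comparator invariant under the y↔z reflection, which makes
square-padding meshes exactly symmetric under the sheet↔normal swap;
tiled meshes are merged before splitting, so shared faces are conforming
by construction.  Cells tile in all three directions; fiber-direction
neighbours share their connection disks as interior facet patches.

Label table: volume labels 0 (matrix) and 1..N (cells); facet labels 1–6
for the box surfaces S1..S6 (S1: x=0, S2: x=Lx, S3: y=0, S4: y=Ly,
S5: z=0, S6: z=Lz), 7 membrane, 8 connection patches.

The `resolution` parameter is the target element diameter (twice the
circumradius).  Counts are ceil-based, so refining the parameter never
coarsens the mesh.  Floors (≥ 4 segments per box side, ≥ 2 matrix rings,
≥ 3 shoulder slabs) maintain element quality near the thin sheet pad;
reported h_max can exceed the target on coarse meshes because a handful
of pad elements are deliberately anisotropic.

## Discretization and solver

Taylor–Hood mixed elements: continuous quadratic displacement,
continuous linear pressure, on the conforming tet mesh; 14-point
degree-5 positive-weight quadrature.  The weak form
`∫ P : grad(v) + q (J − 1) dX = 0` is assembled in numba kernels; the
consistent tangent `dP/dF` comes from complex-step differentiation of the
analytic first Piola–Kirchhoff stress (exact to machine precision).

Stretch/shear protocols FF..NS clamp one face pair completely (the fixed
face to zero, the moved face to a uniform displacement of
magnitude × box extent along the pair axis, directed along the pair axis
for stretches and transversally for shears); the other four faces are
traction-free.  Contraction runs are fully traction-free with the
six-dimensional rigid-body space removed through scalar Lagrange
multipliers enforcing L2-orthogonality.

Each continuation step starts from the previous solution (plus an affine
lifting of the boundary increment) and is solved by a quasi-Newton
iteration: the factorized tangent (SuperLU, minimum-degree ordering in
symmetric mode after symmetric max-row equilibration) is frozen across
iterations and steps, corrected by limited-memory good-Broyden secant
updates, and refactored only on persistent slow contraction; a
backtracking line search rejects steps that invert elements or increase
the residual, and failed steps bisect the continuation increment.
Convergence tolerances: relative and absolute residual 1e-10.

### Pointwise incompressibility and stabilization

With a continuous P1 pressure the incompressibility constraint is weak:
pointwise `J` deviates near the membrane, most strongly in the thin
sheet-pad elements, and on these meshes `max|J−1|` at quadrature points
is of order 1e-2..1e-1 at working loads — not the 1e-6 of the weak
residual.  (The solver reproduces an exact affine incompressible
solution to `|J−1| ≈ 3e-14`, so this is a resolution property, not an
implementation one.)  To keep those elements from collapsing under
strong loading, the solver augments its energy with `κ/2 (J−1)²`
(augmented Lagrangian; the weak constraint equation is unchanged and the
term vanishes as J → 1).  Default κ: 25 kPa for contraction, 200 kPa for
the boundary-driven protocols, which squeeze the pad harder.  Reported
averages are insensitive to κ in this range (peak contraction σ_ff moves
by < 7 % between κ = 25 and κ = 1000).

## Reported quantities

Averages of the Green–Lagrange strain E and Cauchy stress
σ = J⁻¹ P Fᵀ (normal components along f₀/s₀/n₀) are Lagrangian volume
integrals over a subdomain divided by its reference volume, with the
same degree-5 quadrature; available for the whole intracellular space,
each cell, and the matrix.  Surface loads use
`L = ∫_S P N · e dS / ∫_S (F N)·(Fᵀ N) dS` on the reference surface: the
numerator is evaluated variationally (the reaction of the raw residual on
the face indicator — the consistent flux, identical to the quadrature of
the weak form), the denominator by direct facet quadrature, exactly as
written, with no substitution of the deformed area.  Spatial fields are
projected element-locally (L2) onto discontinuous quadratic space and
written as ASCII VTU with per-element nodes, so membrane jumps are
representable.

## Synthetic experiments and calibration

`generate_synthetic_experiment` runs the nine protocols (stretches to
10 %, shears to 40 %) on a chosen mesh, evaluates the normalized loads,
optionally adds independent Gaussian noise (kPa), and writes one CSV per
mode (`displacement_mm, force_N`) plus a dimensions JSON — a stand-in
with the structure of block stretch/shear force–displacement data, so the
calibration pipeline runs without downloads.  The reader converts back
via `λ = 1 + d/L_axis` and `load = force / A_ref`, dropping
negative-displacement rows.  What this does not emulate: real tissue
heterogeneity, compressive branches, hysteresis, or measurement drift —
passing recovery tests shows the estimation machinery is consistent, not
that real data will be fit well.

The objective is the square root of the summed squared differences
between experimental and simulated loads over all retained points of all
modes (unweighted), with simulated curves interpolated linearly in
stretch; simulator failures at extreme trial parameters return a large
finite penalty (1e4 kPa) so bounded optimization can continue.  Fitting
uses L-BFGS-B inside [0.01, 40] per parameter, optionally multi-start
(log-uniform draws) because the surface has local minima; a `free`
argument restricts which parameters vary.  Repeated evaluations reuse
the assembled space and warm-start every (mode, step) state from the
previous evaluation — path independence makes this a pure runtime
optimization.

Sobol sensitivity uses the classic Saltelli cross-sampling design
(N(D+2) evaluations; scrambled Sobol' base sample, seeded), the
Saltelli-2010 first-order and Jansen total-order estimators, and
bootstrap confidence intervals.  Default parameter ranges [0.1, 30]⁶.

## Problem sizes used by the shipped checks

The acceptance computation runs the single-cell 5.0 μm mesh
(≈ 9.5k tets, ≈ 43k dofs) contracted to the transient peak in five
continuation steps.  The test suite exercises the same run once, plus a
shortened-cell fixture (30 μm body, 12 μm diameter) for solver,
calibration and sensitivity properties, and coarse default-geometry
meshes for geometry/convergence checks.

## Known limitations

* Pointwise incompressibility is weak (see above); the configured
  1e-6 tolerance on `max|J−1|` at quadrature points is met only by
  states that are exactly representable (e.g. homogeneous) and is
  reported honestly otherwise.
* The activation transient's peak is the single most influential unknown
  for contraction stresses (see the caution above).
* Structured extrusion produces anisotropic elements in the 1 μm sheet
  pad; stretch protocols beyond ~10 % on coarse meshes rely on the
  κ-stabilization for robustness.
* The pressure space is continuous across the membrane, so pressure
  jumps there are smeared; discontinuous-pressure variants are out of
  scope.
* Distributed-memory solves are out of scope; the largest practical
  problems on one CPU are a few hundred thousand dofs.
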