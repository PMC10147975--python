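# Methods

This note records the models, numerical choices and validation design behind
`ecogforward`, in the order the pipeline runs.

## Phantoms and oracles

All validation runs on concentric-sphere phantoms. A `SpherePhantomSpec`
labels each voxel by the innermost sphere containing its center (no partial
volumes — deliberately, because the forward mesh is one element per voxel, so
label and element geometry coincide exactly). Synthetic diffusion tensors are
D = R diag(λ) Rᵀ with per-class eigenvalues and a constant, radial or
tangential fiber direction field; seeded Gaussian noise is added to the six
unique components. Defaults emulate literature values (mm²/s):
CSF (3.0, 3.0, 3.0)e-3, GM (0.9, 0.7, 0.7)e-3, WM (1.6, 0.4, 0.4)e-3, noise
SD 5e-5. These give MD separation CSF vs parenchyma of ≈ 2.2e-3 and FA
separation WM ≈ 0.7 vs GM ≈ 0.15, i.e. the contrast the two-stage classifier
exploits; the noise level is a realistic tensor-fit uncertainty, far below
the class separations.

Two independent analytic solutions validate the solver:

* **Infinite homogeneous anisotropic medium.** Closed form; also the
  singularity potential of the full-subtraction source model, and the source
  of its analytic gradient used in the right-hand-side quadrature.
* **Multilayer sphere series.** For a dipole at radius b inside the innermost
  region, the potential in region j is Σₙ (Aⱼ rⁿ + Bⱼ r^-(n+1)) in two
  angular channels, Pₙ(cos θ) for the radial moment and Pₙ¹(cos θ) cos φ for
  the tangential moment. Per degree n the 2L−1 unknown layer coefficients
  solve the interface continuity (potential and normal current) and
  insulating-boundary conditions; radii are nondimensionalized by the outer
  radius so powers rⁿ stay O(1) up to n ≈ 200. Truncation default 80 terms
  with an early stop when the term ratio drops below 1e-10; self-convergence
  (60 vs 120 terms) is asserted in tests to 1e-8. Evaluation requires
  |p| > b (expansion about the center), which all use sites satisfy.

Limitations of the phantoms: no cortical folding, no skull inhomogeneity, no
MRI intensity artifacts (synthetic T1 is a two-class Gaussian mixture at
most). Passing tests therefore demonstrate correctness of the numerics and
the processing logic, not segmentation robustness on clinical images.

## Images

Internal world frame is LPS throughout; STL/fcsv files in RAS are converted
on read by negating x and y. Voxel centers sit at
`origin + direction @ diag(spacing) @ index` (0-based, node-centered NRRD
convention). The NRRD reader/writer covers the subset this pipeline uses
(scalar/label/mask volumes, 3-vectors, `3D-symmetric-matrix` tensors;
raw/gzip/ascii encodings; measurement frames applied on load). Gzip streams
are written with a fixed mtime so reruns are bit-identical.

Otsu's threshold uses a 128-bin histogram over [min, max] by default and
reports the optimal cut edge; the bin count is configurable because the
threshold of any given dataset depends on the binning. Component labels are
assigned in raster order of each component's first voxel, and mask dilation
is a Euclidean-distance-transform test in world mm, so a 4.4 mm offset at
1.1 mm spacing spans exactly 4 voxels.

## Surfaces and electrodes

Marching cubes runs on the Gaussian-smoothed (σ = 0.8 voxels) binary mask:
the raw staircase isosurface overestimates area by ~8%, while the smoothed
surface is within ~0.3% (area) and ~1.5% (volume) of the analytic sphere at
1 mm spacing. "Perpendicular" electrode projection is implemented as
closest-point projection (equivalent on smooth convex patches; the
alternative, projecting along sheet normals, is not well defined for
arbitrary meshes). The electrode sheet is the 2-D Delaunay triangulation of
the projected centroids in their best-fit plane, extruded ±t/2 along vertex
normals (default 2 voxels total) into a watertight slab; voxelization is a
ray-parity test in index space with a tiny irrational transverse offset to
avoid edge-exact hits (parity is asserted invariant to the ray axis).

Electrode displacement interpolation onto the selected brain-surface nodes
(default selection tolerance 5–6 mm, configurable) uses MLS. Because
electrode centroids are (nearly) coplanar, a 3-D linear basis would have a
singular moment matrix; the fit therefore runs in the best-fit plane with a
2-D linear basis whenever the source cloud is planar, with an adaptive
support radius. With interpolating weights the load table reproduces the
electrode displacements exactly at the centroids.

## Meshless solver (MTLED)

* **Shape functions.** MLS with a linear basis and quartic spline weight
  w(q) = 1 − 6q² + 8q³ − 3q⁴, node-centered supports of radius 1.8× the local
  nodal spacing (shortest incident background-grid edge). The basis is
  shifted and scaled per evaluation point for conditioning. For essential
  boundary conditions the weights are augmented by 1/q² (singular weights),
  which makes the shape functions interpolate nodal values, so prescribed
  displacements are imposed directly on nodal parameters and satisfied
  exactly.
* **Integration.** 4-point degree-2 Gauss per background tetrahedron,
  α = (5+3√5)/20, β = (5−√5)/20, weight V/4.
* **Consistency correction.** Gauss integration of rational MLS gradients is
  inexact, which would leave ~1e-3–1e-4 relative equilibrium errors even for
  affine fields. Force assembly therefore uses zeroth-order variationally
  consistent test gradients: a constant per-node correction makes
  Σ_ip w ∇̃φ_a equal the boundary integral ∮ φ_a n dΓ for boundary nodes and
  zero for interior nodes (whose test functions are treated as conforming).
  The deformation gradient keeps the uncorrected MLS gradients
  (Petrov–Galerkin pairing). Consequence: any homogeneous (affine)
  deformation state is an exact discrete equilibrium — the linear patch test
  passes to solver tolerance (~1e-13 observed) and reactions of uniform
  states are exact. The forces are no longer the exact gradient of the
  discrete energy; the discrepancy is of quadrature-error size and the
  damped energy decay still holds to high accuracy (asserted over the
  trailing 20% of post-ramp steps with 1e-9 relative slack).
* **Constitutive model.** Compressible neo-Hookean,
  S = μJ^(-2/3)(I − trC/3 C⁻¹) + KJ(J−1)C⁻¹, defaults E = 3000 Pa, ν = 0.49
  (standard soft-tissue values; fully configurable, optionally blended per
  integration point from fuzzy-membership-weighted class moduli on an
  intensity image).
* **Dynamic relaxation.** Explicit central differences with fictitious
  diagonal mass scaled for stability at the chosen Δt (row-sum bound on the
  linearized stiffness with the constrained modulus K + 4μ/3, safety 1.5)
  and mass-proportional damping c = 2√λ with λ a Rayleigh-quotient estimate
  of the lowest mode from successive residual differences. Loads ramp with
  the smooth 3-4-5 polynomial (10τ³ − 15τ⁴ + 6τ⁵); an abrupt step is legal
  but slows convergence. Termination: the max nodal displacement increment
  stays below tol (default 1e-5 mm) for 100 consecutive steps after the
  ramp. Because the mass is fictitious, density only scales the pseudo-time
  units and does not affect the converged static solution.
* **Reaction recovery.** Face-nodal force sums are biased for meshless shape
  functions (subsurface nodes carry boundary mass), so reactions are
  measured as the surface integral of the first Piola–Kirchhoff traction
  over the selected boundary faces — exact for homogeneous states.

## Warping

The forward displacement field is the MLS evaluation of the converged nodal
solution at voxel centers inside the brain mask. A sharp cut to zero at the
mask boundary makes the field non-invertible, so it is extended past the
mask by nearest-voxel values attenuated with a Gaussian (default 2 voxels) —
emulating the smooth decay a full-head model would produce. Inversion is the
fixed point v ← −u(x + v(x)) (defaults: 0.05 mm tolerance, 50 iterations),
with the composition residual enforced only at voxels whose pull-back stays
inside the field domain. Tensor warping resamples the six components
linearly (log-Euclidean interpolation was considered and left out: the
reference workflow this mirrors uses linear interpolation), then applies PPD
reorientation with the local forward Jacobian F = (I + ∇v)⁻¹ computed by
central differences (one-sided at borders); eigenvalues are preserved
exactly by construction and singular Jacobians fall back to the identity
with a warning.

## Tissue classification and conductivity

Fuzzy C-means (m = 2) with deterministic quantile initialization along the
dominant feature axis, one seeded random restart on center collapse, and the
standard alternating updates (the objective Σ u^m d² is non-increasing,
asserted in tests). Classification is two-stage: 2-cluster FCM on MD
(high-MD cluster → CSF), then 2-cluster FCM on FA within the parenchyma
(high-FA cluster → WM); hard labels by maximum membership. Cluster-to-tissue
mapping by center ordering is deterministic.

WM conductivity supports two variants of eigenvalue mapping from the
diffusion tensor: volume-normalized σᵢ = σ_ref·dᵢ/(d₁d₂d₃)^(1/3) (default,
σ_ref = 0.14 S/m — a standard WM reference value; the identity
det σ = σ_ref³ holds per voxel and is asserted to 1e-10) and linear
σᵢ = k·dᵢ. Both appear in the EEG-modelling literature; the configuration
makes the choice explicit. Eigenvalues are floored to keep the image SPD.

## Forward problem

One trilinear hexahedron per masked voxel (shared corners merged, 2×2×2
Gauss). All elements of a voxel mesh are congruent, so the per-Gauss-point
world gradients are computed once — assembly is a single batched contraction.
The pure-Neumann stiffness has the constants as null space; compatibility is
enforced by projecting the constant out of the right-hand side, and the
gauge is zero mean over surface nodes (no pinned node, no local error).

Full subtraction: with σ₀ the conductivity of the dipole's neighborhood
(default: tensor of the host element; homogeneity checked within a
configurable radius, default 3 voxels — the pipeline uses 1.5 voxels because
isolated misclassified voxels at 2–3 voxels from the source are handled
gracefully by the volume term), the load is
b_a = −∫ ∇N_a·(σ−σ₀)∇φ∞ − ∮ N_a (σ₀∇φ∞·n) dΓ over the exterior (air)
boundary faces. The electrode sheet is a volume conductivity (1e-6 S/m), not
a boundary condition. The solver is conjugate gradients with a Jacobi
preconditioner (any SPD preconditioner fits the contract; algebraic
multigrid is out of scope).

Oracle comparisons place the 200 evaluation points on a sphere of radius
R − 2·spacing, just inside the staircase voxel boundary, because the exact
analytic surface is not contained in the voxelized mesh; the series solution
is equally valid there. Both potential vectors are demeaned (common average
reference) before RDM/MAG, since the pure-Neumann FEM and the series fix
their gauges differently; `rdm_mag` itself implements the plain definitions.
Measured at 2 mm voxels (≈ 268k elements): homogeneous sphere RDM ≈ 0.0014,
MAG ≈ 1.003; four-layer sphere RDM ≈ 0.03, MAG ≈ 1.09 (the skull shell is
3 voxels thick — magnitude through the resistive layer is the slowest
quantity to converge). RDM decreases monotonically from 2.5 mm to 1.5 mm.

## Pipeline

`run_all` executes the stage DAG phantom → mask → surface → electrodes →
loads → biomech → warp → classify → fuse → conductivity → hexmesh → forward
→ metrics, writing per-stage manifests with parameter echo and SHA-256
content hashes (deterministic stages are bit-reproducible; NRRD/gzip writers
use fixed timestamps for this reason). The default configuration uses a
scaled-down head (44 mm outer radius, 48³ grid at 2 mm, 4×4 electrode grid,
8 mm biomechanics node spacing) so a full run takes minutes; the metrics
stage reports classification accuracy against the phantom truth and RDM/MAG
of an all-isotropic rerun against the matched multilayer-sphere series (WM
merged into GM so the analytic dipole sits in a uniform innermost region,
and per-element conductivity assigned by voxel radius so the comparison
isolates discretization error). With `biomech.skip`, the warp stage is
omitted and the forward problem runs on the unwarped labels.

## Problem sizes used in the shipped checks

Forward oracles run at 2.5/2.0/1.5 mm on the 80 mm sphere (137k–635k
elements); MTLED benchmarks on a 5³-node unit cube; classification on a 32³
three-layer phantom over 5 seeds; the electrode chain on an 8×8 grid over a
60 mm sphere at 1.25 mm voxels. These sizes were chosen so the whole
verification suite demonstrates convergence behaviour while remaining a
routine desk-scale computation.

## Known limitations

* The series oracle requires the dipole inside the innermost layer and
  evaluation radii greater than the dipole radius.
* Full subtraction assumes local homogeneity around the source; sources
  within ~2 voxels of a conductivity interface need repositioning or a
  different source model (partial integration / Venant are not implemented).
* The meshless solver has no contact mechanics, gravity or skull constraint;
  brain shift is driven purely by the prescribed electrode displacements.
* FCM classification operates on diffusion invariants only; T1-based tissue
  segmentation is out of scope.
* Voxelized geometry means staircase boundaries; accuracy near thin shells
  is resolution-limited (quantified by the four-layer benchmark).
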