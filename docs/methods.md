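# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish. Units: lengths are in model units, stresses in
units of the dermis Young's modulus (E_dermis ≡ 1), and time in units of the
growth rate (β = 1 unless set otherwise).

## Morphoelastic model

Tissue growth is modelled with the multiplicative decomposition
`F = Fe · Fg`. The growth part is prescribed per layer and saturates in
time,

```
Fg(t) = I + λN s(t) N⊗N + λT s(t) (I − N⊗N),   s(t) = 1 − exp(−β t),
```

where `N` is the outward surface direction *in the reference configuration*
(stored per element and never updated during deformation), `λN` and `λT` the
final relative growths along and transverse to `N`, and `β` the saturation
rate. Only the elastic part stores energy; the material is compressible
neo-Hookean,

```
Ψ(Fe) = μ/2 (tr(Fe Feᵀ) J^(−2/3) − 3) + K (J − ln J − 1),  J = det Fe,
σ     = μ J^(−5/3) dev(Fe Feᵀ) + K (1 − 1/J) I,
μ = E / 2(1+ν),   K = E / 3(1−2ν).
```

The closed-form stress is verified in the test suite against central finite
differences of Ψ through `σ = J⁻¹ (∂Ψ/∂Fe) Feᵀ` (relative error < 1e−5 over
100 random elastic states), and is objective under rotations to 1e−10.

By default only tangential growth is used (`λN = 0`); the normal component
is retained in the interface because it is physically meaningful and cheap
to keep configurable.

### Discretization and solver

Linear (P1) tetrahedra with a single quadrature point. Nodal forces follow
from the first Piola–Kirchhoff stress of the grown energy
`Jg Ψ(F Fg⁻¹)`; a one-element bending study (bilayer curl against the
bimetal-strip closed form) shows the discrete bending stiffness is within
~20% of the continuum value at two element layers per lamina, which is the
resolution used for film-wrinkling studies. Poisson ratios above 0.45 are
rejected: single-point linear tets lock near incompressibility.

The quasi-static solution solves damped Newtonian dynamics with fictitious
lumped unit nodal masses:

1. **Growth ramp** (viscous phase): semi-implicit Euler with drag
   coefficient `damping_coefficient` (default 1.0/time) while `βt` rises to
   `growth_ramp_end` (default 5, i.e. ≥ 99.3% of saturation). The time step
   defaults to a stability estimate `cfl · 2/√k_max` from the stiffest node,
   with the growth-stiffening factor `(1+λ)²` included.
2. **Symmetry-breaking kick**: at the end of the ramp every free degree of
   freedom is perturbed by a seeded Gaussian of amplitude
   `perturbation × mean edge length` (default 1e−4). Applying the kick
   *after* the ramp matters: a kick at t = 0 decays during the stable ramp
   and can leave a bifurcating system stranded on the unstable flat branch.
3. **FIRE relaxation**: after the kick, relaxation uses FIRE-style adaptive
   damped dynamics (velocity–force mixing, adaptive time step up to
   `fire_dt_max_factor × dt`, velocity reset on uphill power, per-step
   displacement capped at 5% of the mean edge, backtracking on element
   inversion). This is still damped second-order dynamics, at a small
   fraction of the steps of constant-coefficient relaxation.
4. **Convergence**: the run is accepted when the residual force stays below
   tolerance (`force_tolerance`, or `rel_force_tolerance ×` the post-ramp
   peak residual) for `confirm_steps` consecutive steps. The confirmation
   window is essential near bifurcations: a slowly growing buckling mode can
   sit below any fixed tolerance for thousands of steps; requiring the
   residual to *stay* low rejects such false equilibria.

Mesh-scale boundary conditions: the rigid muscle core is realized as fixed
displacement on the dermis–muscle interface nodes (equivalent to meshing a
rigid solid, without its conditioning cost). The slab generator can also
impose roller (symmetry) side boundaries — nodes on lateral faces slide in
their face plane. These emulate a laterally infinite slab; without them, the
free edges inject a deterministic long-wavelength response that swamps a
near-onset wrinkling instability. With rollers, the measured buckling onset
strain (≈ 0.057 for stiffness ratio 30, ν = 0.3) and the post-onset
wavelength (0.675 vs 0.677 predicted) match classical film-on-substrate
theory.

### Contact

Self-contact is a node–triangle penalty: a linear spring of stiffness
`contact_stiffness` (default 10) acts when a surface node comes within
`contact_range` (default half the mean edge length) of a non-neighbouring
surface triangle, with the reaction distributed barycentrically. Candidates
are refreshed every `contact_rebuild` steps from a kd-tree with per-triangle
search radii; triangles touching the node's topological two-ring are
excluded. A deeply folding dome keeps a positive surface clearance
(verified post hoc by exact point–triangle distances).

## Fold networks and the pattern metric

The epidermis surface of a deformed mesh is reduced to a planar graph:

1. Per-vertex principal curvatures by least-squares quadric fitting over
   two-ring neighbourhoods in the outward-normal tangent frame. Sign
   convention: a unit sphere has κ = +1; fold valleys have κ_min < 0.
2. Valley mask: vertices with κ_min below its q-quantile (default q = 0.3)
   and below zero (with a small scale-relative tolerance so flat surfaces
   give empty masks).
3. The masked vertices are projected along the viewing axis, rasterized at
   0.7× the median edge length, morphologically closed, thinned to a
   unit-width skeleton, and traced into a graph (junction pixel clusters and
   endpoints become nodes; corridors become polyline edges, smoothed with a
   short moving average so raster staircasing does not inflate arc length —
   a circle's perimeter is recovered to ~0.1%). Degenerate one-pixel
   self-loops at junctions are dropped.
4. Simplification merges degree-2 chains (conserving arc length exactly)
   and iteratively prunes spurs shorter than `spur_fraction` (default 0.02)
   of the toepad length.

Cycles ("domains") are the interior faces of the planar embedding, obtained
by the rotation-system face traversal with geometric edge ordering; faces
with positive signed area are interior. An edge belongs to a cycle iff it
appears exactly once on some interior face walk; bridges and spurs
(traversed twice) are the *incomplete* edges. The metric vector is

```
c1 = Σ cycle perimeters / toepad length
c2 = Σ incomplete edge lengths / toepad length
```

with the toepad length taken as the extent of the projected surface outline
along its principal axis. Samples are compared by Euclidean distance after
per-component standardization by inter-sample mean and standard deviation
(fitted once per study on a fixed sample set). Both components are invariant
under rigid in-plane motion and under joint uniform scaling of the network
and the toepad length.

## Nuclei detection and layer densities

Bright nuclei in a 3D stain volume are detected from the signal principal
curvatures k₁ ≥ k₂ ≥ k₃ — eigenvalues of the negated Gaussian-smoothed
Hessian (smoothing σ = 2 voxels by default, near the nucleus radius) — via
the blob score `ks = (k₁⁺k₂⁺k₃⁺)^(1/3)`, which vanishes on edges, sheets and
dark structure. Voxels with `ks > k_threshold` form 26-connected components;
each component's unweighted voxel centroid is one cell. The default
threshold is half the analytic ks of an isolated reference blob,
`0.5 · A s³/(s²+σ²)^{5/2}` for amplitude A and blob width s. For large
volumes the implementation fuses one Gaussian smoothing pass with a
finite-difference Hessian and a closed-form symmetric eigensolve in a single
numba sweep (a 144-megavoxel volume runs in ~25 s in ~2 GB); the
`signal_curvatures` API keeps the analytic Gaussian-derivative route.

Layer densities are sampled on a lattice (spacing half a box) with a cube of
`box_edge = 80` voxels clipped by the volume bounds and intersected with the
layer: density = centroids inside the clipped region / clipped voxel count.
The proliferation contrast is `100 · (mean_epi − mean_derm)/mean_derm`.

**Study conditions.** The synthetic-volume generator defaults encode the
contrast-recovery study: a 185-voxel epidermis band over dermis in a
(400, 600, 600) grid, dermal density 5·10⁻⁵ cells/voxel³, epidermal excess
23%, Gaussian nuclei of σ = 2 voxels at peak 10 over unit-variance noise
(SNR 10). The grid is sized from the Poisson error budget: ~4000 nuclei per
layer put the counting-noise floor of a five-seed mean contrast near ±1.2
percentage points, comfortably inside the ±3-point acceptance band. At
these densities the method itself carries a ≈ −1.2-point systematic (close
nuclei pairs merge into one component, costing the denser layer slightly
more; plus a small clipped-box boundary effect), which the tests absorb
within the stated tolerance rather than correct post hoc.

## Bayesian calibration

`simulate_and_score` composes solver → fold network → metric → normalized
distance into a deterministic objective (NaN on simulation failure, replaced
inside the optimizer by 10× the worst successful value so the surrogate
learns to avoid the region). `bayes_optimize` is a seeded Gaussian-process
surrogate (Matérn 5/2 with automatic relevance, white-noise term,
normalized inputs/outputs) with expected-improvement acquisition over random
plus best-point-local candidates, Latin-hypercube initialization, and a
patience stopping rule (default: stop after 500 iterations without
improvement, cap 3000; scaled-down defaults of 100/300 are used in tests).
`staged_fit` runs the two-stage protocol: five parameters against the
control target, then the three epidermis parameters against the treated
target with the dermis optima frozen.

**Known limitation — desk-scale identifiability.** At the problem sizes this
package runs on one CPU (a ~15k-element dome, ~2–10 s per simulation), the
treated dome folds into a handful of radial spokes: the pattern has no
closed cells, so c1 ≡ 0 and the objective effectively collapses to a single
component. The level set {c2 = c2(target)} is then a surface in the
three-dimensional treated parameter space, and the jagged, multistable
dependence of the metric on parameters creates spurious near-zero minima far
from the generating parameters. Under these conditions the scaled-down
recovery study does *not* reliably localize the epidermis stiffness and
growth (the corresponding end-to-end test documents this failure rather than
hiding it). Recovering parameters through this objective requires patterns
with many folds — meshes and iteration budgets orders of magnitude beyond a
desk run. All other end-to-end checks (constitutive oracle, wrinkling
wavelength, growth fixed points, contrast recovery, metric exactness, seed
stability of the fold metrics) pass at desk scale.

## Synthetic data: what it does and does not show

The generators emulate the *structure* of the real inputs — layered
geometry with a rigid core, nuclear-stain volumes with layer-dependent
Poisson nuclei, labyrinthine target networks — with seeded reproducibility.
They do not emulate: anatomically accurate toepad shapes, spatial
inhomogeneity of growth within a layer, imaging artifacts (attenuation,
anisotropic PSF, stair-step voxelization), nuclei shape variability or
clumping beyond Poisson placement, or manual-segmentation noise in target
networks. Passing tests therefore establish the correctness and internal
consistency of the algorithms at realistic scales and noise levels, not
their accuracy on real light-sheet data.

## Numerical defaults at a glance

| parameter | default | notes |
|---|---|---|
| β (growth rate) | 1 /time | sets the unit of time |
| growth_ramp_end | 5 | ≥ 99.3% of saturation |
| damping_coefficient | 1 /time | ramp-phase drag |
| cfl | 0.25–0.4 | fraction of the explicit stability limit |
| perturbation | 1e−4 × mean edge | symmetry-breaking kick |
| rel_force_tolerance | 1e−3 | of post-ramp peak residual |
| confirm_steps | 3000 | anti-false-equilibrium window |
| contact_range | 0.5 × mean edge | penalty onset distance |
| contact_stiffness | 10 | dermis-modulus units |
| curvature quantile q | 0.3 | valley mask |
| spur_fraction | 0.02 | of toepad length |
| smoothing σ (cells) | 2 voxels | ≈ nucleus radius |
| k_threshold | 0.5 × reference-blob ks | detection operating point |
| box_edge | 80 voxels | density estimation |
| ν cap | 0.45 | locking guard |
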