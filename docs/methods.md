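# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `ribalign`, and what the synthetic phantom does and does
not tell you about real data.

## The problem being modelled

A patient is CT-scanned supine before surgical stabilization of rib
fractures; in the operating room they lie in a (different) lateral
position. A navigation system builds a 3D model from the CT, a user
marks a small set of bony landmarks on the model (`L_model`) and
measures the corresponding points on the patient (`L_patient`), and a
rigid transform fitted to these pairs carries every fracture annotation
onto the patient. Three error sources limit accuracy: landmark
localization noise (fiducial localization error, FLE), the non-rigid
torso deformation between poses, and everything downstream of the model
itself (display optics, hand marking) — the last of which is out of
scope here. The package simulates the first two and measures their
effect on fracture localization.

## Synthetic torso phantom (`ribalign.phantom`)

**Geometry.** The torso is an ellipsoid of soft tissue; its default
semi-axes (195, 112, 335) mm reproduce a 390 × 224 × 670 mm torso
mannequin. The world frame is RAS (+x patient right, +y anterior, +z
superior), torso centred at the origin. Ribs are elliptical-arc tubes
(default radius 6 mm) following the torso cross-section at 0.88 of its
local semi-axes — roughly 12 mm below the skin, as for real ribs — with
azimuthal gaps of 14° at the sternum and spine and `n_rib_pairs`
(default 8) levels spanning z/c ∈ [−0.25, 0.55]. An optional scanner
bed is a slab 8 mm behind the posterior skin (so it is a separate
connected component, as in a real scan). Intensities are Hounsfield
units: air −1000, soft tissue 40, bone 700, bed 300, plus additive
Gaussian noise (default SD 15 HU, a typical soft-tissue noise level for
a standard-dose CT). Voxel spacing defaults to 2 mm isotropic; the
experiment suites use 4 mm, which keeps a full-torso run in seconds
while still oversampling every structure (ribs are three voxels thick).

**Landmarks.** The ten candidate bony landmarks (suprasternal notch,
left/right AC joints, xiphisternum, left/right ASIS, C7, T1,
left/right PSIS) are mapped to fixed parametric sites on the skin
ellipsoid (a table of left-right and inferior-superior fractions in
`phantom.py`); only their names are anatomically prescribed, the
coordinates are this package's convention. Midline landmarks have
exactly zero lateral coordinate and bilateral pairs are exactly
mirror-symmetric, which several tests exploit.

**Fractures.** Candidate fracture sites sit on a fixed arc-length grid
(20 mm spacing) along each rib centerline; a seeded permutation picks
the requested number, so increasing the count extends the selection
without reshuffling earlier picks. Requests beyond the grid's capacity
raise rather than crowd sites together.

**Pose change.** `simulate_pose_change` applies, in order: (1) a
smooth non-rigid field — a single-axis sinusoidal bend
`dx = A·sin(π·ẑ/2)` plus a linear shear `dy = A/2·ẑ`, where ẑ is the
normalized longitudinal coordinate — which emulates the supine-to-
lateral torso deformation with one amplitude knob and is exactly zero
at `A = 0`; (2) a ground-truth rigid transform (Euler angles +
translation); (3) i.i.d. isotropic Gaussian noise of the given per-axis
SD on each point, emulating fiducial-marker placement and detection
error. Noise is applied *after* the rigid motion so the exact rigid
component is returned for oracle tests. Everything is a pure function
of (spec, seed).

## Segmentation (`ribalign.segmentation`)

Clinical-grade pipelines of this kind typically remove the scanner bed
and segment bone with trained 2D segmentation networks; `ribalign`
ships self-contained classical methods behind the same module
contract: bed removal keeps only the largest above-air
26-connected component (the body) and resets everything else to the
scene's air value (idempotent by construction), and bone is an HU
threshold (default 150 HU) inside the body mask with components under
50 voxels discarded. A learned segmenter can be dropped in behind the
same signatures.

The body threshold follows the stated rule *t = min + 0.20·(max −
min)* — a linear fraction of the intensity **range**, not a percentile
of the intensity histogram (the histogram reading is available as
`method="histogram"`). The mask is the largest 26-connected component
above `t`, morphologically closed, with 8-connected hole filling per
axial slice; `t` is recorded in the mask metadata. Series
concatenation places slices on a common z grid by world coordinate;
where scans overlap the later series wins (the rule is arbitrary but
fixed and documented).

On the noiseless phantom, body and bone masks match the construction
labels with Dice exactly 1.0; at 20 HU noise Dice stays ≥ 0.95. These
are properties of the phantom's clean HU separation — real CTs have
partial-volume effects, contrast variation and pathology that no
threshold handles this well.

## Meshing (`ribalign.meshing`)

Pipeline order is fixed: extract → smooth → remove-internal → simplify.

- **Extraction**: Marching Cubes on the mask after a light Gaussian
  pre-smoothing (σ = 1 voxel). Contouring a raw binary grid inflates
  surface area by ~9% (staircase artifact); the smoothed field places
  edge crossings sub-voxel accurately and brings a voxelized sphere's
  area within 0.2% of analytic. If smoothing would erase the mask
  (features thinner than the kernel) the raw binary field is contoured
  instead, so a single-voxel mask still yields a closed mesh.
- **Smoothing**: uniform-weight (umbrella) Laplacian, default 10
  iterations at weight 0.5. It strictly shrinks convex closed surfaces;
  interior vertices of a regular planar patch are fixed points of a
  single iteration.
- **Interior-face removal**: ambient occlusion with a deterministic
  Fibonacci-sphere direction set (default 64 rays/face, no RNG), ray
  origins offset 0.1 × mean edge length along the face normal to avoid
  self-hits. "Always in shadow" is read as occluded fraction = 1.0
  (configurable down for noisy meshes); the operation is idempotent
  because deleting interior faces cannot shadow a face that already saw
  open sky. Ray casting is an in-package chunked Möller–Trumbore
  (exact, memory-bounded).
- **Simplification**: in-package Garland–Heckbert quadric edge-collapse
  decimation (cheapest edge first, optimal collapse position from the
  combined quadric, collapses that would flip a surviving face's normal
  are skipped). A 15k-face voxel sphere decimated to 1k faces keeps
  its enclosed volume within 0.3% and its bounding box within 2%.
- **Fracture indicators**: 2 mm-radius cylinders from the fracture
  point through the skin along the smooth surface normal (vertex
  normals of the nearest face, interpolated barycentrically at the
  projection), extending a configurable length beyond the skin.

Nearest-point-on-mesh queries use a k-d tree over face centroids (plus
the faces touching the nearest vertex) followed by exact point-triangle
distances; this is exact whenever the true nearest face is among the
candidates, which holds with large margin on these CT-scale meshes.

## Rigid registration (`ribalign.registration`)

The solver is the classical closed form for the least-squares rigid
alignment of paired point sets: centroids → centering → cross-
covariance `H` → SVD → `R = V·diag(1,1,det(VUᵀ))·Uᵀ` → `T = q̄ − R·p̄`.
The determinant term handles the reflection case, which the narrative
descriptions of this algorithm usually omit; returning a reflection
silently would corrupt the alignment, so the case is corrected and
flagged. No scale is estimated — the objective contains none. A
minimum of 3 non-collinear landmarks is required (matching the clinical
eligibility rule of at least three available candidate landmarks);
degeneracy is detected by a singular-value ratio below 1e-9 and raises
instead of returning a least-norm guess. All computation is double
precision; correspondences are by explicit shared names in order, never
searched.

Two independent checks accompany the solver. A brute-force oracle
scans a z-y-x Euler grid (translation set optimally per candidate by
centroid alignment, objective reduced to maximising `tr(R·H)`) and must
never beat the SVD solution. And the closed-form expected TRE for
isotropic FLE,

```
TRE²(r) ≈ (FLE²/n) · (1 + (1/3) Σₖ dₖ²/fₖ²),
```

with `dₖ` the target's distance from principal axis k of the landmark
configuration and `fₖ` the landmarks' RMS distance from it, agrees with
10,000-draw Monte-Carlo simulations through the solver to better than
1% at torso-scale target sites — validating the noise simulator's
error propagation end to end.

## Evaluation (`ribalign.evaluation`)

"Shortest surface distance" is implemented in two modes, because a
physical ruler measurement on a curved body wall is ambiguous between
following the skin and spanning the chord: **geodesic** (default) is
the shortest path on a graph holding the mesh edges plus, for every
adjacent triangle pair, the unfolded straight segment between their
opposite vertices when it crosses the shared edge — these shortcuts
remove most of the zig-zag overestimation of a pure edge graph and put
the antipodal path on a sphere within 0.05% of the great circle;
**euclidean** is the straight line between the two surface projections.
Query points are projected to the surface (tolerance 10 mm by default)
and joined to their triangle's vertices as temporary nodes, which
preserves symmetry and the triangle inequality exactly (verified on
thousands of random triples). For repeated queries against fixed
sources, a per-source distance field costs one shortest-path sweep.

Accuracies are reported in cm as mean ± sample SD (n−1); records
without a measured distance are excluded from the mean but kept in the
localization-rate denominator, mirroring the study design in which
distances exist only for fractures fixed during surgery. A single
measurement reports SD 0 with an explicit flag. The two-sample test is
Welch's (unequal variances) — the plain "two-sample t-test" is
underspecified and Welch is the safer default; group comparisons use
one-way ANOVA with Tukey HSD adjusted p-values from the studentized-
range distribution, cross-checked against statsmodels in the tests.

## Experiment pipeline (`ribalign.pipeline`)

One experiment = one phantom (model side, built once) × a list of
deformation conditions ("positions") × replicates. Replicate `r` at
position `j` uses seed `base_seed + 1000·r + j`, so conditions are
independent and extensible without reshuffling. The patient-side skin
mesh depends only on the deformation (not the landmark noise), so one
surface-distance evaluator per position is shared across replicates; in
geodesic mode one distance field per true fracture site serves all
replicates. A mapped fracture that cannot be projected onto the skin
within tolerance (possible at high landmark noise) is recorded as *not
localized* — the simulated analogue of a fracture indicator appearing
outside the patient's body. Outputs (records CSV, report JSON, config
echo, SHA-256 manifest) are byte-deterministic given config + seed.

## Problem sizes and tolerances

The test and acceptance suites run the full-size torso at 4 mm voxels
(≈1.3 M voxels, ≈100k-face skin mesh, no decimation), 16 fractures × 3
positions for protocol checks, 200 replicates per noise level for the
noise-response curve, 200 constructed motions for exactness, a
2° Euler grid for the optimality oracle and 10,000 draws for the TRE
comparison. Exactness is asserted at 1e-9 (rotation entries,
translation mm, FRE), analytic mesh/geodesic comparisons at the few-
percent level their voxelization/triangulation warrants, and the
TRE/Monte-Carlo agreement at 10%.

## What the phantom does not capture

The generator emulates geometry and first-order noise, not CT physics:
no beam hardening, metal or motion artifacts, no partial-volume blur
beyond voxelization, no respiratory motion, no anatomical variation in
landmark sites, and torso deformation is a smooth low-order field
rather than articulated posture change. Passing tests therefore
demonstrate the correctness of the *computational pipeline* and the
error propagation of the *alignment procedure*; they say nothing about
segmentation robustness on clinical CTs or about human-in-the-loop
error sources (display optics, hand marking, palpation), which
dominated the gap between phantom and clinical accuracy in the physical
studies.
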