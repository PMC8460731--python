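# Methods

`mrhist` restores the spatial mapping between in vivo MR imaging and 2D
histology that destructive histopathology processing breaks, and uses the
restored mapping to evaluate imaging biomarkers against volumetric
histological annotations. This note describes the models, the parameters
that matter, the synthetic study the package validates itself on, and the
design choices made where the design was genuinely open.

## The registration model

Tissue processing destroys spatial correspondence in three steps —
excision/fixation (D1), gross slicing into ~3 mm blocks (D2), and
microtome sectioning (D3) — and the pipeline estimates one restoring map
per step:

* **R1 (histology → blockface).** Each stained section is registered to
  the blockface photograph taken at the same microtome depth, correcting
  the in-plane distortion of sectioning, staining and mounting. Both
  inputs are binary tissue segmentations. The registration minimizes the
  sum-of-squares matching energy

      E = ∫_Ω ‖I₁(φ⁻¹(x)) − I₀(x)‖² dx

  over an affine map and then a diffeomorphism, the latter by greedy
  gradient flow: the pointwise force `2 r ∇I₁(φ⁻¹(x))` is smoothed by
  spectrally inverting a Cauchy–Navier elasticity operator
  `L = −α∇² − α∇(∇·) + γI` (α = γ = 1; the operator's coefficients are a
  package choice) and the map is composed with a small backtracked step
  along the smoothed velocity, coarse-to-fine over an image pyramid
  (factors 4, 2, 1 by default; 2, 1 at the phantom's resolution). All
  accepted steps decrease the energy; the accumulated steps form an
  explicitly invertible velocity-flow map.

* **R2 (blocks → ex vivo).** The 50 µm blockface image series of each
  block is aligned (translation-only, camera jitter is a shift) and
  stacked into a 3D volume; marching cubes on the stacked segmentation
  gives each block's surface, which is split into head/foot cut faces and
  exterior using face normals plus the known cut-plane depths. Starting
  from an anchor block, each neighbor's facing cut surface is registered
  — affine, then diffeomorphic — to the already-deformed facing surface
  of the previous block, propagating outward; finally the deformed
  exterior surfaces are joined and registered to the ex vivo tissue
  surface, giving one global chain applied after the per-block chains
  (single pass; per-block transforms are not re-solved).

* **R3 (ex vivo → in vivo).** Feature surfaces visible in both T2w
  spaces (tumor boundary, vessels) are registered as a union — affine,
  then diffeomorphic — giving the excision/fixation correction. No
  landmarks drive any registration; landmarks only evaluate it.

Surface registration throughout uses the **currents** representation: a
mesh is the sum of vector-valued Dirac masses carrying area-weighted face
normals η(p) at face centers c(p), compared in the norm of a reproducing
kernel Hilbert space with a scalar Cauchy kernel
`k(x, y) = 1/(1 + ‖x−y‖²/σ²)`. The dissimilarity needs no point
correspondence and is exactly zero only when the two currents coincide.
Deformations are flows of stationary velocity fields spanned by Cauchy
kernels at control points (the moving mesh's vertices, subsampled above a
cap), integrated over [0, 1] with explicit Euler steps; the energy adds
the RKHS norm of the velocity as the smoothness penalty. Inverse maps
solve each Euler step by fixed-point iteration, so forward/inverse
consistency is at iteration tolerance rather than O(dt). The area-weighted
(rather than unit) normal convention keeps the norm stable under mesh
refinement.

The full chain for a section composes R1, an embedding of the section
plane at its depth, the per-block and exterior chains, and R3; every
element is invertible, so in vivo MR can equally be resampled onto any
histology plane. Volumetric histology labels are built by pulling target
voxels back through the inverted chains and interpolating per-section
signed-distance fields linearly along the sectioning axis (thresholded at
zero); contributions of adjacent blocks blend over the outermost
half-spacing of their section ranges.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| face-matching kernel σ | 1.0 mm | data-term scale for cut-face pairs |
| exterior/R3 kernel σ | 2.0 mm | data-term scale for large surfaces (order of block thickness) |
| velocity kernel σ_V | 3 mm (faces), 8 mm (exterior), 6 mm (R3) | smoothness scale of the deformation |
| velocity regularization λ | 3·10⁻³ (faces), 10³ (exterior), 0.3 (R3) | RKHS-norm weight |
| flow steps | 5 | Euler steps over unit flow time |
| Cauchy–Navier α, γ | 1.0, 1.0 | elasticity smoothing of the image-flow velocity |
| binary presmoothing | 1 voxel | gives binary segmentations an intensity gradient |

Two of these encode deliberate asymmetries found during phantom
calibration. The **face affine stage is translation-only**: a flat,
nearly featureless cut face cannot identify rotation or scale, and an
unconstrained affine reliably finds collapse or rotation minima that beat
the true transform; the regularized kernel flow supplies the non-rigid
part. The **exterior-to-ex-vivo stage is essentially rigid**
(translation-dominated, λ = 10³): the stitched block mesh and the ex vivo
mesh come from different sources at ~1 mm resolution and differ
systematically (seam-band rounding, staircase mass); a flexible exterior
flow chases those differences and measurably biases the interior mapping
inward, while the per-block face chains are already accurate and
unbiased. Seam bands (±0.9 mm around each interior cut plane) are
excluded from the exterior data term for the same reason. The pipeline
anchors the reconstruction at the *middle* block, which minimizes
propagation length; `choose_center_block` also offers the
largest-exterior-area rule.

In the general affine surface stage, a small identity-anchored ridge
(10⁻² of the initial energy) pins the null directions of degenerate
inputs and is annealed to zero in a final refinement pass so it cannot
bias directions the data identifies; the stage runs a coarse-to-fine
kernel schedule (4σ → 2σ → σ) for capture range.

## The synthetic study

Because no study data accompany the method, the package ships a
destructive-histopathology simulator that is itself first-class, tested
code. It renders an agar-embedded tissue surrogate — an ellipsoid with
smooth low-order boundary irregularity, an internal necrosis lesion
nested inside a tumor blob, and tubular vessels — entirely as analytic
implicit functions, then replays the destructive steps with *known*
transforms: a smooth random excision diffeomorphism plus a small rigid
perturbation (2 mm magnitude, 7 mm smoothness), equal near-3 mm blocks
with independent small rigid + smooth deformations (0.8 mm, 5 mm
smoothness), blockface images every 50 µm with simulated paraffin
show-through under two lighting conditions, and histology sections every
250 µm under independent smooth 2D distortions (0.4 mm). Every stage
image is produced by mapping its grid through the exact ground-truth
chain, so landmarks and labels are consistent across stages to the
transform-inversion tolerance, and the ground-truth chain is the oracle
for all recovery tests. Deformation magnitudes were chosen so the
per-stage ground-truth displacements bracket sub-millimeter stage errors;
stage intensity palettes differ so no registration can succeed by
intensity identity.

Default problem sizes keep the full study tractable on one CPU: volumes
at 1 mm isotropic voxels (~26×26×22 mm), sections at 0.5 mm pixels,
block surfaces extracted at 0.5 mm (faces) and 1 mm (exteriors). At these
sizes the complete pipeline — stacks, ~60 section registrations, block
reconstruction, feature registration, composition and label building —
runs in roughly two to three minutes.

What the phantom does *not* emulate: photorealistic staining appearance,
tears and folds (distortions are smooth), intensity-driven segmentation
error (stage segmentations are ground truth, standing in for the
semi-automatic segmentation of the real workflow), partial-volume and
bias-field effects beyond a smooth multiplicative field, and anatomy
beyond one muscle-like compartment. Passing tests therefore demonstrate
that the *registration and composition machinery* recovers known
transformations under realistic geometry and noise — not that
segmentation or staining variability are handled.

On the default study the pipeline reaches mean stage TREs of roughly
0.12–0.15 mm (R1), 0.8–1.1 mm (R2), 0.2–0.3 mm (R3), a composed
histology-to-in-vivo error of 0.6–1.0 mm, and necrosis-label DICE of
0.89–0.94 against ground truth (observed over several phantom seeds; the
test suite asserts the fixed-seed values it computes). The dominant error
source is R2: at 1 mm data resolution, mesh discretization noise is the
same order as the 0.8 mm block deformations being estimated, a regime the
original high-resolution workflow does not face.

## Numerical choices and degenerate inputs

* Pairwise currents sums (energy, gradients, flow backpropagation) run in
  exact float64 compiled kernels; evaluation matches the naive double sum
  to ~1e-14 relative.
* Diffeomorphism validity (positive Jacobian at every node,
  inverse-consistency below 0.1 voxel) is checked by construction helpers
  and asserted in pipeline tests; folding during surface-flow
  optimization triggers amplitude halving, then failure.
* Facing cut surfaces carry antiparallel outward orientations; the
  orientation of the moving current is aligned to the target before
  matching, otherwise coincidence is an energy *maximum*.
* Marching-cubes surfaces are optionally Taubin-smoothed; face-matching
  meshes stay unsmoothed because smoothing rounds each block's rim toward
  its own interior and biases facing faces toward each other.
* Empty inputs (sections before the tissue starts, blocks sliced past
  the sample, flat images) are detected and skipped or rejected with
  named errors; blockface frames without tissue keep identity alignment.
* All stochastic elements derive from one seed; reruns with the same
  configuration reproduce all numeric outputs.

## Known limitations

* R2 accuracy at 1 mm resolution is meshing-noise limited; the stage
  errors do not reach the sub-0.3 mm regime attainable with ~20 µm
  blockface imaging.
* The exterior stage corrects only translation-scale assembly drift by
  default; genuinely large stacking errors (several mm of block
  misplacement) would need a looser regularization than the default.
* Landmark-based evaluation underestimates spatially structured error;
  the label-overlap metrics are the stricter check and are reported
  alongside.
* The 2D-slice-correlation comparison reproduces the orderings of the
  3D-vs-2D analysis as a statistical property; magnitudes are specific to
  the phantom's conditions.
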