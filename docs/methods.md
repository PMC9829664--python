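# Methods

`fracrecon` reconstructs the 3D shape of a (possibly fractured) proximal
femur from two simulated radiographs taken at −45° and +45° about the
vertical axis (the Judet pair).  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
phantoms do and do not establish.

## Problem setting and data model

All volumes are rank-3 arrays indexed `(x, y, z)` with `z` the vertical
(superior–inferior) axis, 0-based voxel indices, and voxel spacing in mm
(isotropic 1 mm by default).  Ground truth is a label volume over three
classes: background 0, bone 1, and the fracture-gap "auxiliary" class 2.
Bone fragments are carried as ordered, pairwise-disjoint binary masks;
after any operation that may split the bone, fragments are relabelled from
26-connected components, ordered by decreasing size with ties broken by the
smallest linear index (26-connectivity because oblique fracture surfaces
produce diagonal adjacencies that 6-connectivity would over-split).

## Femur phantoms

No public CT cohort of fractured femurs exists, so the package generates
its own study population.  A phantom is the union of five analytic solids —
a vertical shaft capsule, a neck capsule leaving the shaft top at the
neck–shaft angle (default 130°, anatomically constrained to (90°, 180°)),
a head sphere and greater/lesser trochanter spheres — voxelised by
centre-inclusion on the grid.  Bone intensity is N(700, 100²) HU and the
soft-tissue background N(40, 20²) HU, placing bone far above the 63–193 HU
band used to refill fracture gaps.  Cohorts draw shaft/neck/head radii and
the neck–shaft angle uniformly from ranges scaled to the grid, with one
derived seed per sample so regeneration is bit-identical.  The default test
grid is 32³–64³ at 1 mm.

Each phantom also carries a map from AO/OTA fracture-location codes to
axis-aligned boxes: 31A trochanteric, 31B femoral neck, 31C femoral head,
32 diaphyseal.  The 32 box deliberately sits on the lower diaphysis so it
cannot touch the trochanter bumps.

What the phantoms do **not** model: cortical/trabecular substructure, the
pelvis and contralateral femur, realistic soft-tissue anatomy, or displaced
fractures.  Passing tests therefore demonstrate the machinery — label
synthesis, augmentation algebra, network trainability — not clinical-grade
accuracy on hospital radiographs.

## Auxiliary class (fracture-gap labeling)

The gap between nearby fragments is synthesised morphologically: every
fragment is dilated with a discrete sphere of radius `r` (all integer
offsets of Euclidean norm ≤ r; default r = 2 voxels), the pairwise
intersections of the dilations are united, and the bone union is
subtracted.  Consequences that the tests pin down: an intact bone yields an
empty gap; the gap is disjoint from every fragment; it is invariant under
fragment relabelling; it grows monotonically with `r`; and two fragments
more than `2r` voxels apart produce nothing.  Dilation clips at the grid
boundary — fragments near the border never wrap.  `r` is in voxel units
(morphology is grid-native); the dilation sphere at r = 1 has 7 offsets and
at r = 2 has 33.

## Fractural augmentation

Fractured training samples are manufactured from intact ones in five steps.

1. **Rough surface.**  A self-affine height field h(u, v) is synthesised
   spectrally: complex Gaussian noise shaped by a radial power-law
   amplitude q^−(1+H) between frequency cutoffs (defaults 0.02–0.4
   cycles/voxel), inverse-FFT'd, de-meaned and rescaled to an RMS roughness
   σ.  The resulting power spectral density follows q^−(2+2H); with the
   default Hurst exponent H = 0.8 the radially averaged log–log slope is
   −3.6, which the tests recover within ±0.3.  Defaults: σ = 2 voxels,
   slab thickness t = 2 voxels (thick enough that the r = 2 gap dilations
   from both fragments meet across it).
2. **Placement.**  An AO code picks a region box; the surface centre is
   drawn uniformly inside it, with the surface normal tilted from vertical
   by a per-code range (shaft 0–20° near-transverse, neck 30–70° oblique,
   trochanteric/head 0–30°) and uniform azimuth/spin.
3. **Rasterisation.**  The placed slab is rasterised directly on the
   volume grid: each voxel is mapped into the surface frame and kept when
   its height above the bilinearly interpolated sheet is within half the
   effective thickness.  The effective thickness adapts to the local sheet
   slope and the slab orientation (1-norm of the rotated normal axis) so
   the digital slab is always 26-separating.  This choice is deliberate:
   nearest-neighbour resampling of a pre-voxelised thin slab opens
   staircase pinholes through which the two would-be fragments stay
   26-connected, and bone splits then almost never succeed.  A
   nearest-neighbour mask-resampling path is kept (`place_surface_mask`)
   for working with externally supplied voxel surfaces.
4. **Split.**  The gap is the intersection of bone and slab; the fragments
   are the 26-components of bone minus slab.  Exactly: union(fragments) ∪
   gap = bone and union(fragments) ∩ gap = ∅.  Draws that fail to produce
   at least two fragments of ≥ 1% of the bone volume raise a typed
   rejection and are resampled (bounded retries, default 25; measured
   single-draw split rates 53–100% depending on AO code).
5. **Intensity refill.**  Gap voxels of the intensity volume are replaced
   independently with Uniform(63, 193) HU — the soft-tissue band observed
   at fracture sites, mean 128 HU; everything outside the gap is copied
   bit-exactly.  Continuous uniform sampling is used (integer vs continuous
   is immaterial downstream).

Only nondisplaced fractures can be manufactured: fragments never move.

## Radiograph simulation

Digitally reconstructed radiographs use parallel-beam geometry: the volume
is rotated about z (trilinear interpolation), attenuation — HU + 1000
clamped at 0, a water-referenced proxy — is summed along y and scaled by
the voxel spacing, and each image is min–max normalised to [0, 1].
Parallel beams keep the rotation/projection commutation exact enough to
test against an oracle and suffice at phantom scale; scatter, beam
hardening and detector noise are out of scope.  The Judet pair is
(−45°, +45°); a rotational-error parameter offsets the second view to probe
sensitivity to non-orthogonal acquisition.

## Reconstruction network

Two per-view encoder–decoder towers feed a fusion path.

* **Encoder** (per view): a 3×3 stem convolution, then one dense block per
  pyramid level — four layers of instance-norm → ReLU → 3×3 convolution
  whose outputs concatenate onto everything before them (growth rate g) —
  followed by 2×2 max-pooling between levels.  L levels halve the extent
  down to `image_size / 2^(L-1)`.
* **Decoder** (per view, coarse-to-fine): at each level the upsampled
  previous decode (kernel-2 stride-2 transposed convolution) is
  concatenated with the same-scale encoder features and convolved to
  exactly `extent(i) × C3D` channels; reshaping channels into depth then
  yields a cubical 3D block of C3D channels.  The reshape is a bijection
  (its inverse reproduces the 2D features exactly).
* **Fusion**: the second view's blocks are rotated 90° about the vertical
  axis (swap the two horizontal axes, flip one — applying it four times is
  the identity) to align with the first view's frame.  At the deepest level
  the two blocks are concatenated and convolved; at shallower levels the
  2×-upsampled previous fusion joins the concatenation.  Each fusion stage
  is a configurable number (default 2) of 3×3×3 convolution → instance
  norm → ReLU.  A final 1×1×1 convolution produces 2 or 3 class channels;
  softmax gives per-voxel probabilities and arg-max (ties to the lower
  class) the label volume.

The reference depth is L = 7 at 128² inputs; all widths (base channels,
growth, C3D, fusion channels) are configuration because no reference values
exist for them, and the test suite exercises L ∈ {3, 4, 5} at extents
16–64, where a forward pass takes well under a second on one CPU.  Weights
are He-initialised from a seeded generator, so identical seeds give
identical networks.

The network runs on a compact reverse-mode autodiff engine written on
NumPy (`fracrecon.autodiff`): stride-1 same-padding correlations via
sliding-window tensordot, non-overlapping kernel-2 stride-2 transposed
convolutions via einsum, 2× max-pooling with tie-splitting subgradients,
instance normalisation with the standard closed-form backward, log-softmax,
and Adam.  Every primitive's gradient is finite-difference checked in the
test suite.

## Loss

Voxel-wise weighted focal loss.  Label volumes are dominated by background
(roughly 9800 : 200 : 1 background : bone : gap on fractured samples), so
cross-entropy is modulated by (1−p)^γ to suppress well-classified voxels,
with per-class weights.  Defaults γ = 2 and w = (0.15, 0.25, 0.6) for
(background, bone, gap); two-class runs renormalise the first two weights.
Each class channel is scored one-vs-rest against its one-hot target and the
per-class focal terms are **averaged** over voxels before weighting, so the
weights are scale-free with respect to volume size.  The loss is the
standard nonnegative form −(1−p)^γ log p (and −p^γ log(1−p) for negatives);
probabilities are clamped at ε = 1e−7.  At γ = 0 with unit weights the loss
reduces exactly to one-vs-rest cross-entropy, and at p = 0.5, γ = 2, y = 1
it equals 0.25·ln 2 ≈ 0.1733 — both asserted in tests.

## Training and evaluation

`FracReconNet` is a scikit-learn style estimator: Adam (default learning
rate 1e−4, β₁ = 0.9, β₂ = 0.99; the scaled-down experiments in the test
suite use 3e−3 to converge within their step budgets), per-step shuffled
sampling, optional validation-based early stopping (patience 10
evaluations, best-validation weights restored), and deterministic behaviour
given `random_state`.  Three variants are compared: the plain two-class
network, the three-class network with the auxiliary class, and the latter
additionally trained on augmented fractured samples (one augmented sample
per intact training sample by default, drawn with per-sample seeds).

Metrics follow the evaluation convention that the auxiliary class is merged
into the background in both prediction and ground truth, so all variants
are scored on the bone class alone.  IoU is defined as 1 when both masks
are empty.  ASSD takes surface voxels (face-neighbour definition, grid
boundary counts as outside), computes both directed nearest-surface
distances via Euclidean distance transforms with anisotropic sampling, and
divides the summed distances by the total surface count; voxel centres
rather than meshes are the surface representation.  Empty masks are an
error for ASSD.  Cohort reports aggregate mean ± SD per sample type
(intact / nondisplaced / displaced) and overall; per-fold means feed a
paired two-sided t-test, with the zero-variance-difference case flagged
explicitly (t = 0, p = 1 for identical lists; ±inf with a warning for a
constant nonzero difference).

Sample types are stratified over folds (per-type fold counts differ by at
most one).  The scaled-down experiments the tests run are: memorisation of
3 phantom pairs by an L = 4, 32² network (600 steps, bone IoU reaches
> 0.9 and the predicted gap voxels sit adjacent to the true gap), and a
3-fold cross-validated comparison of the two-class and three-class variants
on a 12-phantom cohort (6 intact + 6 nondisplaced, 350 steps per fit).
These sizes were chosen so each experiment completes in minutes on a single
CPU while still exercising every architectural element at full fidelity.

## Known limitations

* Phantom-scale only: no claim transfers to hospital radiographs without
  retraining on real data.
* Displaced fractures cannot be synthesised by the augmentation (fragments
  never move), so the displaced stratum exists only if such data is
  supplied externally.
* The DRR model is parallel-beam without noise; rotational-error sweeps
  probe geometry sensitivity, not detector physics.
* The NumPy engine is single-threaded BLAS-bound; the L = 7 / 128³
  reference configuration is supported by the code but not by the test
  suite's time budget.
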