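# Methods

## The classification problem

Leaf shape is one of the most discriminative cues for plant species
identification, but solving a sparse-coding problem over a dictionary of
*all* training images (classical SRC/WSRC) scales poorly: the per-sample
cost of the l1 minimization grows with the full training size n.  The
two-stage scheme implemented here (DWSRC) first routes a test image to one
of m+1 groups of shape-similar training images and then sparse-codes it
only on that group's subdictionary of roughly n/m atoms.

## Model

**Atoms.**  Every image is reduced to a 32x32 contour raster (values in
[0, 1]); flattened row-major it is one column of a dictionary.  A config
switch (`contour_atoms=False`) substitutes filled silhouettes, since both
representations appear in the literature; contours are the default.

**Similarity.**  s(x, y) = exp(-||x - y||^2 / (2 beta^2)), the Gaussian
kernel on the Euclidean (Frobenius) distance between rasters.  Kernel
widths are set by the midrange rule beta = (d_max + d_min)/2 over a set of
cross distances: all (training, representative) pairs for the partition
width, and the (test, candidate-atom) pairs — recomputed per test sample —
for the weighting width beta1.

**Partition.**  Given m representative "typical shape" images t_j, a
training image joins the group of its most similar representative provided
s >= T (default T = 0.5); otherwise it falls into the overflow group m+1.
Each group's members form subdictionary A_j.  Routing a test image y uses
the same rule with a looser threshold T1 (default 0.1) and falls back to
the overflow group when nothing is similar enough.

**Sparse coding.**  On the routed subdictionary A_r the coefficient vector
solves

    min_a ||y - A_r a||_2^2 + mu ||W_r a||_1,        mu = 0.001,

with W_r = diag(w_i), w_i = exp(+||y - x_i||^2 / (2 beta1^2)): the weight
*grows* with distance, so far atoms are penalized harder and the code
stays local.  (The exponent's sign is kept positive as in the source
formulation of this scheme; with the midrange beta1 the largest weight is
bounded by e^2, and a hard cap of 1e12 guards pathological widths.  The
thresholded-similarity scheme used by classical weighted SRC — w_i =
s(x_i, y) above a threshold, 0 below — is available as
`weight_scheme="thresholded_similarity"`, where a zero weight simply leaves that
coordinate unpenalized.)

**Decision.**  For each species c present in the routed group, the code is
restricted to that species' columns and the size-normalized residual
m_c(y) = ||y - A_r a^c|| / n_c computed, where n_c is the species' atom
count in the group; the label is the argmin (ties to the lexicographically
smallest label).  The SRC/WSRC baselines use the raw residual without the
1/n_c factor, as is conventional for them; a config flag (`decision`)
exposes either rule in all three classifiers for ablation.

## Solver

Cyclic coordinate descent with per-coordinate soft thresholding at
mu*w_i/2, warm-started at zero, Gram matrix precomputed, stopping when the
largest coefficient change in a sweep falls below `tol` (1e-8 by default;
the objective convention carries no 1/2 factor, so with A = I the solution
is soft-thresholding at mu/2).  On rare instances with nearly collinear
columns cyclic descent crawls along a flat valley; if `max_iter` is
exhausted, a FISTA (accelerated proximal-gradient) refinement runs from
the best iterate and is kept only if it lowers the objective.  Against an
independent convex solver (split-variable box-constrained QP under
L-BFGS-B) the returned objective agrees to ~1e-14 relative on random
10x20 instances.

## Preprocessing chain

1. Grayscale conversion (ITU-R 601 luma).
2. Background suppression: pixels below 30 (8-bit scale) are zeroed.
3. Median filter, disk footprint of radius 10, auto-capped at
   floor(min(h, w)/4) so tiny images (leaf databases go down to ~29x21)
   survive.
4. Footstalk removal: narrow structures are the difference between the
   mask and its opening with a disk of radius `stalk_width` (default 5);
   the connected chain with the greatest skeleton length is cut off if at
   least `min_stalk_length` (10) long, and the largest remaining component
   is kept.
5. Alignment: the principal axis of the foreground (second central
   moments) is rotated to vertical; the 180-degree ambiguity is resolved
   by the sign of the along-axis third central moment (skewness), placing
   the broad (base) side down.  A half-mass rule was rejected: splitting
   at the centroid makes the two halves nearly equal by construction, so
   its sign is noise-driven and flips a substantial fraction of samples
   within a species.  Isotropic foregrounds skip rotation with a warning.
6. Contour extraction: Canny (sigma 1, hysteresis 0.1/0.3 of the intensity
   range) on a zero-padded frame — without padding, boundaries touching
   the tight-cropped image border are silently suppressed — followed by
   morphological thinning, because an ideal binary step produces two
   equal-gradient pixels and non-maximum suppression keeps both.
7. Tight crop to the contour extents and bilinear resize to 32x32 (with
   the antialias prefilter: subsampling a one-pixel curve without it makes
   the raster hypersensitive to sub-pixel shifts), rescaled to [0, 1].

The square resize deliberately discards the aspect ratio (the same choice
the source pipeline makes); consequently shape families must differ in
contour structure, not elongation, to remain separable — this drives the
synthetic-family design below.

## Synthetic leaf generator

Shapes are radial Fourier contours r(theta) = r0 (1 + sum a_k cos(k theta
+ phi_k) + tooth + notch): low-order harmonics span the classical leaf
taxonomy (elliptic, cordate, lobed), a high-frequency low-amplitude cosine
produces dentate margins, and a localized basal indentation models the
cordate sinus.  The hierarchy is family (fixed prototype parameters) →
species (family plus a random excursion of harmonics 2–4, sd 0.02, aspect
log-sd 0.08, notch log-sd 0.2) → sample (relative noise, default sd 0.05,
on every amplitude, a random in-plane rotation, optionally an attached
3x40 px stalk).  Every family carries a first-harmonic base/apex asymmetry
(0.18–0.22) — as real leaves do — which anchors the flip rule; species
excursions avoid order 1 and the lobed orders so neither the orientation
anchor nor the family signature is eroded.  Randomness is hierarchical
(`SeedSequence` spawn keys per family/species/sample), so adding species
never shifts earlier draws.

The default benchmark is 4 families (elliptic, cordate, 3-lobed, 7-lobed)
x 3 species x 20 samples at noise 0.05, seed 7 — 12 species, 240 images,
sized so the full evaluation fits on a laptop-scale budget.  What passing
tests on it show: the pipeline is rotation-tolerant, the partition groups
by gross shape, and the two-stage classifier recovers species that are
separable in raster space.  What they do not show: robustness to real
photographs (venation, texture, shadows, occlusion), to families separated
only by aspect ratio (destroyed by the square resize), or to the extreme
intraclass variability of field collections.

## Numerical choices and degenerate inputs

- Exact similarity ties during partitioning go to the lowest group index;
  argmin label ties go to the lexicographically smallest label.
- A test sample identical to every candidate atom (beta1 undefined) is
  classified by exact match.
- Zero-norm dictionary columns keep a zero coefficient.
- Empty groups are dropped at build time and skipped at routing time
  (fallback to the overflow group; routing fails only if that is empty
  too).
- `nnz` counts entries with |a_i| > 1e-8.

## Known limitations

- Species absent from the routed group can never be predicted for that
  sample; routing consistency, not routing "correctness", bounds accuracy.
- The size normalization 1/n_c biases the decision toward species with
  many atoms in the routed group when residuals are comparable.
- The positive-exponent distance weights and the thresholded-similarity
  weights disagree about whether near or far atoms are penalized; both are
  implemented as printed in their sources and selectable, not reconciled.
- Footstalk removal assumes a single dominant narrow protrusion; compound
  leaves and petioles wider than `stalk_width` are out of scope.
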