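# Methods

`legcomp` quantifies lower-extremity body composition from chemical-shift-
encoded (CSE, "Dixon") MRI.  A CSE acquisition reconstructs co-registered
fat-weighted, water-weighted and in-phase contrasts; the package partitions
each axial slice into subcutaneous adipose tissue (SAT) and skeletal muscle,
aggregates per-slice volumes into ten height-normalized "decades" along the
leg, and compares groups with rank-based statistics.  A parametric two-leg
phantom generator with exact truth labels makes every stage testable without
patient data.

## Segmentation model

The pipeline is a classical, fully deterministic five-step procedure applied
independently to every axial slice:

1. **Leg boundary.**  Chan–Vese active contours (the region-based,
   edge-free energy, here in its morphological formulation) on the in-phase
   image, which is bright over the entire leg and nearly flat inside it.
   The contour is initialized from the global-Otsu foreground dilated by
   3 px; this is deterministic, anatomy-agnostic, and converges well within
   the default 100 iterations.  The converged foreground's brighter phase is
   taken and its holes filled, producing a mask bounded by the outer leg
   perimeter.  Anything bright outside the legs (arms, hands in the field
   of view) is still foreground at this step; it is excluded downstream
   because only the leg mask is applied to the fat/water images.
2. **Fat/water classification.**  Smooth multiplicative intensity
   inhomogeneity (bias field, from shim imperfections and distance to
   isocenter) defeats a single global threshold in the extremities.  Each
   leg-masked contrast is therefore binarized against a per-pixel threshold
   equal to the local mean in an `s x s` neighborhood (replicate padding at
   image borders) scaled by `2*(1 - sensitivity)`; the default sensitivity
   of 0.5 makes the threshold the local mean itself.  The kernel side
   adapts to the anterior–posterior leg extent `HBOX` (the height of the
   bounding box of the leg mask):

   `s = 2 * floor(HBOX * c / 2) + 1`, with scalar `c = 3/4` by default.

   The floor-and-double form keeps `s` an odd positive integer.  A kernel
   of three quarters of the leg height always mixes tissue classes, so the
   local mean sits between the fat and water intensity levels; a small
   kernel would misclassify background, and a whole-image kernel would stop
   adapting to leg size.
3. **Muscle.**  The leg mask is eroded by a 2×2 square (removing the thin
   skin rim) and intersected with the water mask; the fat mask is
   subtracted; objects smaller than 10 px are removed; holes smaller than
   18 px are filled (bone holes are larger and survive); morphological
   closing with a 2 px disk (ankle-to-knee region) or 4 px disk (thigh
   region, where muscle cross-sections are larger and smoother) smooths the
   mask; and remaining enclosed holes (bones) are flood-filled, giving the
   *filled muscle* mask.
4. **SAT.**  The filled muscle mask is subtracted from the fat mask;
   morphological opening with a 2 px disk severs thin bridges between SAT
   and marrow; connected components with circularity `4*pi*A/P^2 > 0.80`
   are removed (marrow is round, SAT is an elongated annulus); components
   smaller than 10 px are removed.
5. **Final muscle.**  Fat-weighted components not classified as SAT
   (intermuscular fat, marrow) are subtracted from the filled muscle mask.

Manual corrections (e.g., knee-joint slices) enter as per-slice override
masks that replace the automated result verbatim.

### Parameters

All tunables live in `SegmentationConfig` with the defaults above
(`ac_iterations=100`, `kernel_scalar=0.75`, `threshold_sensitivity=0.5`,
`skin_erosion=2`, `min_object_area=10` px, `max_hole_fill_area=18` px,
`closing_radius_lower=2` px, `closing_radius_upper=4` px,
`sat_opening_radius=2` px, `circularity_cutoff=0.80`).  Area and kernel
parameters are in pixels and are therefore resolution-bound: they were
developed at a 2.07 × 1.35 mm in-plane protocol, and the pipeline logs a
warning when the input spacing deviates from that by more than 25%.
`upper_region_fraction` (default 0.5) maps the calf/thigh closing-radius
split onto a stitched volume as a slice-index fraction, since stitched
volumes no longer carry acquisition-stack identity.

### Numerical and design choices

- *Even erosion kernel.*  A 2×2 structuring element has no center pixel;
  the erosion is anchored at the kernel's top-left element, fixed for
  reproducibility.  Consequently the erosion trims only two of the four
  boundary directions — an inherent property of even kernels, documented
  rather than hidden.
- *Thresholding ties.*  A pixel equal to its local threshold counts as
  foreground (`>=`), so an exactly uniform bright region inside the leg is
  foreground; pixels without signal are never foreground.
- *Hole filling.*  "Holes < 18 px" fills any background component fully
  enclosed by foreground whose area is below the cutoff; larger enclosed
  holes (bones) are preserved until the explicit flood-fill.
- *Circularity.*  Perimeter uses the Crofton estimator, which is unbiased
  for digitized smooth shapes; naive pixel-edge or marching-squares contour
  lengths systematically mis-score small discs (a radius-4 disc would fall
  below the 0.80 cutoff on contour length while scoring 0.886 with
  Crofton).  Interior boundaries count toward the perimeter, which pushes
  ring-shaped SAT components even further below the cutoff — the safe
  direction.
- *Mask invariants.*  After closing, the muscle mask is clipped to the leg
  mask, guaranteeing `SAT ∪ muscle ⊆ leg` and `SAT ∩ muscle = ∅` on every
  slice.
- *Degenerate inputs.*  An all-background slice yields an empty leg mask
  with a logged warning; zero muscle volume flags the SAT-to-muscle ratio
  as undefined (NaN) rather than 0 or infinity.

## Volume handling

Whole-body protocols acquire several axially stacked volumes whose slice
ranges overlap.  Stitching removes duplicates by *physical slice position*
(within half the slice spacing), not voxel equality, because neighboring
reconstructions of the same position need not be bit-identical; when two
stacks supply the same position the more superior stack's copy is kept
(superior stacks are nearer isocenter in a head-first acquisition).  The
analyzed ankle-to-thigh range is selected from user-supplied landmark slice
indices — deliberately manual, matching the semiautomated design; there is
no automatic landmark detection.

## Composition metrics

Per slice, SAT and muscle volumes are voxel counts times the voxel volume
(mL), summed over both legs (lower-extremity lipedema is approximately
bilateral and symmetric).  Slices are partitioned into ten decades with
boundaries at `floor(d*n/10)`; ranges are disjoint, exhaustive, and differ
in size by at most one.  Decade 1 is the ankle end; decade 3 approximates
the superior calf and decade 7 the midthigh.  Decade values are unweighted
means of per-slice metrics; slices with undefined ratio are excluded from
(not zero-filled into) the ratio mean, since zero-filling would bias ankle
decades where muscle can vanish.  Limb circumference is measured on the
subject-left leg (image-right under the radiological convention; exposed as
a flag) as the length of the leg mask's outer contour in physical
millimetres, respecting anisotropic in-plane spacing.  The binary mask is
Gaussian-smoothed (sigma = 1 px) before marching squares because the raw
staircase contour overestimates a smooth perimeter by several percent;
after smoothing, discs and rectangles are recovered within ±1.5%.

## Validation and statistics

Segmentation accuracy is the Dice similarity coefficient
`DSC(A, G) = 2|A ∩ G| / (|A| + |G|)` between the algorithm mask `A` and
ground truth `G`, evaluated on the middle slice of decade 3 (calf) and
decade 7 (thigh); empty-vs-empty is defined as 1.0 (both raters agree there
is no tissue) and logged.  Per-group DSC means are compared with a
two-sided pooled-variance Student's t-test after a Shapiro–Wilk normality
screen (both delegated to scipy).

Composition metrics are compared per decade with the Mann–Whitney U test,
implemented in-package: midrank tie handling, a tie-corrected normal
approximation for Z, exact enumeration of the permutation null when both
groups have fewer than 8 members (exactness matters at toy sizes; cohort
sizes of 13–15 sit safely in normal-approximation territory), and the
two-sided exact p defined as the null probability of a U at least as
extreme as the observed one on either side.  No continuity correction is
applied; under a 13-vs-15 null the empirical type-I rate at alpha = 0.05 is
0.038.  The rank-based effect size is `r = |Z| / sqrt(n1 + n2)`, bounded in
[0, 1]; Z comes from the normal approximation even when p is exact, because
r is only defined through Z.  No multiplicity adjustment is applied across
decades, matching the analysis this package mirrors.

## Synthetic phantoms

Each slice holds two elliptical legs (per-slice eccentricity jitter in
0.80–0.90 avoids trivially circular SAT that the circularity filter would
wrongly target), with a 1 px skin rim, a SAT annulus, muscle interior, and
fat-bright marrow discs — two bones in the calf half (tibia/fibula analog),
one in the thigh half (femur) — plus one or two ~2 px intramuscular fat
arcs that exercise the step-5 subtraction on thin structures.  The default
grid is 96 × 192 in-plane at 2.07 × 1.35 × 3.0 mm, 60 slices, with leg
radius tapering 22 → 30 px (ankle → thigh) and SAT thickness 6 → 9 px.

Intensities: bright tissue 1.0, off-component residual 0.08, skin 0.15 on
the water image (dermis has short T2* and is near-residual on gradient-echo
water images; with noticeably brighter skin, surviving skin arcs would be
bridged into the muscle mask across thin SAT by the disk closing — a
failure mode real water contrasts do not exhibit).  In the clean limit,
thresholding each contrast at half the tissue intensity recovers the truth
foreground exactly, which anchors the contrast synthesis in tests.  The
bias field is multiplicative, `1 - a*(0.5*(1 - g) + 0.5*z/(n-1))` with `g`
a centered in-plane Gaussian bump and a linear slice-axis ramp (in-plane
shading plus isocenter drop-off); default amplitude 0.3.  Noise is additive
Gaussian (sigma 0.05 of the tissue intensity), clipped at zero.

Cohort generation draws, per subject: a body-size scale in U(0.85, 1.15)
applied to both leg radius and SAT thickness (height/frame spread — it
dominates circumference variance but cancels out of the SAT-to-muscle
ratio), an independent SAT-thickness jitter in U(0.85, 1.15), and a small
leg-shape jitter in U(0.97, 1.03).  These widths put the circumference and
SAT-volume dispersion in the range reported for real control/lipedema
cohorts.  "Lipedema-like" subjects multiply SAT thickness (default 1.75×)
and expand the leg radius by the same increment, leaving the muscle
compartment untouched: disproportionate outward fat deposition with
preserved musculature.  This construction reproduces the qualitative
clinical pattern — SAT volume and SAT-to-muscle ratio separate the groups
in every decade, muscle volume does not, and the ratio's effect size
exceeds the circumference's.

### What the phantom does and does not emulate

It emulates complementary fat/water contrast, a bright in-phase channel,
smooth bias fields, additive noise, tapering anatomy, bones with fat-bright
marrow, and thin intramuscular fat.  It does **not** emulate Rician
magnitude noise (additive Gaussian is used; the pipeline is
magnitude-threshold based and insensitive to the distinction at the tested
SNR), chemical-shift or motion artifacts, partial-volume boundary voxels
(tissue edges are crisp), SAT texture such as the nodularity described in
lipedema, or knee-joint geometry.  Passing on phantoms therefore
demonstrates the correctness of the mask algebra, the adaptive-threshold
logic under bias, and the statistical machinery — not clinical-grade
accuracy on patient data, where Dice scores would be lower.

## Problem sizes used in the shipped checks

The test suite and the acceptance script choose desk-scale sizes: Dice
validation uses ten 60-slice phantoms at default bias/noise; the noiseless
volume-recovery check uses one 20-slice phantom; the cohort analysis uses
13 + 15 subjects at 20 slices each; the null-calibration check uses 1000
simulated 13-vs-15 cohorts.  All randomness is seeded; identical seeds give
bit-identical phantoms, masks and tables.

## Known limitations

- Pixel-unit parameters do not transfer across resolutions; the kernel
  scalar in particular may need re-tuning for other protocols.
- The even-kernel skin erosion trims only two boundary directions; skin
  suppression in practice relies on skin being dark on the water contrast.
- Circumference requires the two legs to be separable at the image midline;
  slices with merged legs are flagged and skipped.
- DSC group t-tests assume near-normal per-group DSC distributions; the
  Shapiro–Wilk screen only logs violations, it does not switch tests.
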