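# Methods

## Forward augmentation

Both augmentations act about a cut center *O*. In deployment *O* is
"the approximate center of the tumor"; the package derives it from the
ground-truth mask as the foreground centroid, rounded half-up and
clamped so every part of the cut is non-empty. This is deterministic
and mask-derivable, but it means the method needs some lesion
localization at test time — a limitation of the approach itself, not of
this implementation.

**HV cutting** splits the image at the snapped center (r0, c0) with a
half-open rule: rows ≥ r0 and columns ≥ c0 belong to the bottom/right
quadrants. This makes the four parts an exact tiling (no duplicated
pixels), which in turn makes the augmentation → inversion round trip
bit-exact. Each quadrant is zero-padded to a square of side
max(height, width), anchored at the corner containing *O*, so that
after mirror expansion *O* sits exactly at the generated image's
center. The expansion places the quadrant in the output block matching
its original position and fills the other three blocks with its
left-right, up-down and point mirrors; the result is invariant under
both axis flips.

**Diagonal cutting** first zero-pads the image to a square of side
2·max(r0, H−r0, c0, W−c0) so that *O* is the exact center, then
partitions the square into four cones using pixel-center coordinates
(dy = row + ½ − s/2, dx = col + ½ − s/2): right = {dx > |dy|},
left = {−dx > |dy|}, bottom = {dy ≥ |dx|}, top = {−dy ≥ |dx|}. Pixel
centers make the diagonals pass through the true center, so the
reflections are exact array transposes. Ties on the diagonals are
assigned to the top/bottom cones — any deterministic rule works; this
one keeps left/right strictly inside open cones. A consequence worth
knowing: the expansion of a *left* or *right* cone leaves the diagonal
pixels zero (they have no pre-image in an open cone). This affects a
measure-zero set of pixels, never the reconstruction (top/bottom
estimates cover the diagonals), and is asserted as such in the tests.

Reference augmentations (crop/rotate/mirror) are provided for method
comparison. Crops are sampled uniformly over all windows containing
the lesion's bounding box, seeded; if the bounding box fills the image
the originals are returned with a logged warning.

## Inverse reconstruction

A segmented augmented image contains four mirrored copies of one
quadrant, hence four independent estimates of its mask after inverse
reflection. Per quadrant the estimates are merged by pixel-wise
majority (≥ 2 of 4) — voting suppresses segmentation noise that is not
mirror-consistent. The voted quadrants tile the original frame (HV) or
the padded square (DIAG), so they are assembled into one full-frame
mask whose outer contour — the largest 8-connected component's
boundary, via marching squares at level 0.5 — is the boundary estimate.
One global polar cloud is fitted rather than one spline per quadrant:
per-quadrant contours would contain spurious points along the cut
lines themselves, which carry no information about the lesion
boundary.

Polar conversion uses θ = atan2(−(row − c_r), col − c_c): image rows
grow downward, so negating restores counter-clockwise mathematical
angles. Points coincident with the center (r = 0) carry no angular
information and are dropped with a logged count. The samples are
replicated at θ ± 2π ("triple-period expansion") before fitting, and
only the middle period is evaluated, so the fitted curve has no seam
artifact at ±π.

The fit is a cubic smoothing spline minimizing
p·Σ(r_i − f(θ_i))² + (1 − p)·∫f″², the classical smoothing-spline
trade-off with p ∈ [0, 1]: p = 1 interpolates, p → 0 tends to the
least-squares line. Internally this maps to a roughness penalty
λ = (1 − p)/p. The default p = 0.99 keeps genuine boundary curvature
while absorbing pixel-level contour jitter; p = None selects λ by
generalized cross-validation (the closed-form leave-one-out criterion)
when the noise level is unknown. Duplicate abscissae are averaged
before fitting; fitted radii are clipped at zero. The middle period is
discretized at 360 equally spaced angles by default, mapped back to
(row, col) and rasterized by scan-line polygon fill on pixel centers,
clipped to the image frame.

**Complex mode.** The compensation region
U = [−π, −π+h] ∪ [−π/2−h, −π/2+h] ∪ [−h, h] ∪ [π/2−h, π/2+h] ∪ [π−h, π]
has total measure 8h; the default h = π/9 gives 8π/9 (≈ 44 % of the
circle). Inside U the combined cloud takes the DIAG-derived samples,
outside the HV-derived ones: U is exactly the set of directions along
which the HV cuts run, where HV augmentation severs the boundary and
the trained segmenter is least reliable — and where the DIAG cuts do
*not* run. The assignment is exposed as `u_source` should anyone want
the opposite convention. The combined cloud may be discontinuous at
U's endpoints; no continuity is enforced — the smoothing spline
absorbs the jumps (tested on synthetic discontinuous input). If one
source has no samples in its assigned region, the other fills in with
a logged warning. h must stay below π/4 or the intervals would
overlap; h = 0 degenerates to pure HV reconstruction.

The polar model assumes the lesion is star-shaped about *O* (each ray
crosses the boundary once). Non-star-shaped boundaries are projected
onto their single-valued radius envelope by the sorting + fitting
steps; this is a documented limitation of the representation, not a
failure mode the code guards against.

## Metrics

Dice is computed from per-pixel confusion counts; two empty masks give
Dice 1.0 by convention (a correctly predicted absent lesion should not
score 0), logged when it occurs. The Hausdorff distance is taken
between boundary point sets (foreground pixels with a 4-neighbor
outside the mask) rather than full masks, making it a boundary-placement
measure; units are pixels throughout, as no physical spacing exists
for synthetic inputs. Method comparison uses the two-sided Wilcoxon
signed-rank test paired by case id, significance at p < 0.05; all-zero
differences return p = 1.0 with a warning.

## Synthetic phantoms and segmenters

A phantom is a dark lesion (background mean 0.55, lesion contrast
0.25–0.45 below it) on a speckled background. The outline is a rotated
ellipse (semi-axes 14–30 px in cohorts, ratio up to 2) whose radius is
modulated by harmonics k = 2…5 with total amplitude bounded by the
`boundary_roughness` parameter (default 0.05, cohort range ≤ 0.10) —
star-shaped about its center by construction, verified by ray-casting
in the tests. Speckle is multiplicative log-normal noise
(σ = 0.15–0.35), the standard first-order ultrasound texture model.
Cohorts are pure functions of one master seed with per-case seeds
drawn from it, so regeneration is byte-identical.

What the phantoms do **not** emulate: attenuation and shadowing,
posterior enhancement, heterogeneous internal echotexture, multiple or
border-touching lesions, and real speckle correlation. Passing tests
therefore demonstrate the correctness and internal consistency of the
augmentation/reconstruction machinery — not clinical segmentation
performance, which depends on the trained network that the segmenter
interface deliberately replaces. The perturbed oracle (boundary-band
erosion/dilation of configurable radius, optional random flips,
optionally confined to an angular band about the cut directions) is
the device used to probe the compensation mechanism in isolation.

## Pipeline and problem sizes

The method harness mirrors the usual eight-arm comparison: baseline,
crop/rotate/mirror references and their union, HV, DIAG, and the
compensated combination. With plug-in segmenters there is no training
step, so the baseline and reference arms segment the test image
directly; the reference augmentations are still generated for
bookkeeping. Four-fold cross-validation assignment (seeded shuffle,
round-robin, a 90/10 train/validation sub-split recorded per fold) is
carried along for segmenters that would use it. Default experiment
sizes — 20-phantom cohorts at 128×128, 360 boundary samples — were
chosen as the smallest at which the reconstruction error is clearly
dominated by the method (spline + rasterization) rather than the
discretization, and the full acceptance computation completes in
seconds. Per-case failures are recorded as NaN rows rather than
aborting a run.
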