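# Methods

## Model and assumptions

The pipeline assumes magnitude MR images (all intensities non-negative), one
fat-only image stack plus an anatomy reference in the same spatial domain,
and depots that are bright and connected in the fat image. It makes no
attempt at physics-based correction: B0/B1 inhomogeneity artefacts are
handled by the scripted voxel edits, exactly as an operator would handle
them interactively. No through-plane (3-D) connectivity is used anywhere;
every slice is segmented independently and only the volumetry pools slices.

Two acquisition schemes are supported. For base + fat-suppressed (water)
pairs the fat image is the voxelwise clamped difference `max(base − water,
0)`; negative differences can only arise from noise, so clamping loses no
signal. For 2-point Dixon pairs the standard magnitude combination is used:
`water = (IP + OP)/2`, `fat = max((IP − OP)/2, 0)`. No phase correction or
water/fat swap detection is attempted; scanners that produce fat images
directly can feed them straight in.

## The threshold chain

Background noise `BG = mean + sd` is estimated per slice from voxels sampled
uniformly without replacement from the 8 margin fields (default band width
10 voxels, 100 voxels per field, sample sd with n−1). The estimate is
deterministic given the run seed; each slice uses a seed derived from the
run seed and slice index.

The body mask comes from Otsu thresholding of the anatomy reference. The
Otsu implementation bins intensities into 256 equal-width bins on
[min, max], evaluates between-class variance at every interior bin edge
using exact per-bin intensity sums, and takes the lowest maximizing edge;
foreground is `v ≥ edge`. Keeping only the largest 8-connected object before
hole filling protects the mask against bright margin artefacts. The contour
is every mask voxel 4-adjacent to background or on the image edge.

The adipose threshold is `TC = mean − sd` of the fat-image intensities at
the contour voxels, falling back to `TC = BG + 0.1·sd` when the candidate is
strictly below BG (equality keeps the contour value). The local threshold
marks a voxel iff its value strictly exceeds the clipped-window mean plus
TC. Window extents must be odd for a centred window; the human default
of 50×50 is therefore resolved to an effective 51×51 at call time
while the configured value is echoed unchanged. Window means are computed
with an integral image; at borders the window is clipped and the mean taken
over the in-image part.

Strict `>` versus `≥` at the threshold and the clipped-border convention are
deliberate, documented choices; both only matter on measure-zero ties.

## Edits, depots, reinsertion

Edits are applied to the thresholded binary stack before labelling:
removals and cut voxels go to 0, additions to 1, and relabelling after
editing is mandatory. Objects are labelled per slice with 4-connectivity by
default — required so that one-voxel-wide cut lines actually disconnect
depots — renumbered in raster first-encounter order. Seed points assign
whole objects to SAT (1) or VAT (2); unseeded objects stay 0 and are logged,
which doubles as a noise-object filter. A seed that lands on an unlabelled
voxel is snapped to the nearest labelled voxel within 3 voxels (noise can
erode the exact voxel a seed points at; an operator clicks anywhere inside
the visible object). Cut voxels are reinserted afterwards: each takes the
majority depot among the non-zero values of its 8 in-plane neighbours in the
frozen pre-reinsertion map, ties and isolated voxels defaulting to SAT
(cuts sit at the SAT/VAT interface next to the subcutaneous ring). This
conserves voxel counts exactly: labelled voxels after reinsertion equal the
pre-cut count plus additions minus removals.

An optional convenience heuristic (off by default, and not part of the
reference workflow) assigns any object containing a body-contour voxel to
SAT.

## Agreement statistics

Jaccard differences are pooled over all analysed slices of a subject — one
number per subject and depot — rather than averaged per slice. RVD is
signed, `100·(A − B)/B`, with B the reference. Spearman correlations use
average ranks with the t-approximation for the two-sided p-value (an exact
permutation option exists for n ≤ 9). Bland–Altman differences default to
reference − test; limits of agreement are bias ± 1.96·sd(d), the CI of the
bias uses `t(0.975, n−1)·sd/√n`, and each LoA's CI uses the standard
approximation `SE ≈ sd·√(3/n)`. The proportional-bias test is the Spearman
correlation of the differences against the pair means; the proportional
y-axis mode divides each difference by its pair mean. Normality checks, when
wanted, should use a stock Shapiro–Wilk routine on the differences; the
package does not re-derive one.

## What the phantom emulates — and what it does not

The phantom is an elliptical body with a bright SAT annulus inside the body
border, disk-shaped VAT blobs, and two dark kidneys. Body axes vary ±3 %
across slices. Defaults are the two target acquisition regimes: mouse 256×256 voxels of
0.156×0.156×1 mm, tissue 20,000, fat 30,000, background noise sd 1,500,
CHESS suppression residual 5 %; human 320×240 voxels of 1.234×1.234×2.5 mm,
tissue 150, fat-image level 180 (in-phase fat voxels at 360, below 500
throughout), noise sd 2. Ten slices per subject, matching the analysed
kidney window. Background voxels carry folded Gaussian noise (a magnitude
image cannot be negative); body voxels carry additive Gaussian noise clamped
at zero. The Dixon phantom sets the water content equal to the fat content
at fat voxels, so the out-of-phase magnitude is non-negative and the
combination recovers the intended fat image exactly.

The SAT annulus has two angular gaps totalling ~30 % of the perimeter. Real
subcutaneous rings are lobular and interrupted; computationally this is what
gives the contour intensity distribution a spread, without which
`mean − sd` of a noise-free phantom contour would equal the fat intensity
itself and threshold everything away. When `sat_vat_gap = 0` one deliberately
small blob (0.75× the minimum blob radius — a fat window covering both the
annulus and a large touching blob would locally exceed the threshold margin)
is placed against the annulus, and the suggested cut line is the SAT-side
interface (SAT voxels 4-adjacent to VAT), so the tie-to-SAT reinsertion rule
restores truth labels. Suggested seeds are the maximal-interior-distance
voxel of every post-cut connected component per slice.

The phantom contains no bias fields, no partial-volume edges, no chemical-
shift displacement, no motion, and its depots are geometric primitives.
Passing the recovery tests therefore shows the chain of estimators is
self-consistent and robust to additive noise at study-like contrast; it does
not certify accuracy on real anatomy, where edit effort and partial-volume
voxels dominate the error budget.

## Problem sizes and numerical choices

Recovery experiments use 20 phantoms per species per noise condition, at
full preset image sizes, 10 slices each. The moderate
noise condition sets the background sd to 5 % of the fat-image level. Oracle
equivalence checks run on 32×32 images against per-voxel loop and BFS
implementations; the Otsu check uses exhaustive search over all bin edges.
Volume arithmetic: voxels × (dx·dy·dz)/1000 cm³, exact in double precision
for the preset geometries. All randomness (margin sampling, phantom
generation, synthetic agreement data) flows from explicit integer seeds;
reruns are bit-identical.

## Known limitations

- Otsu thresholding is the plain between-class-variance criterion (with the
  exact-bin-sum convention above); no modified variants are provided.
- Whether background should be estimated once per subject or per slice is
  an open choice; per slice is implemented (it adapts to slice-dependent
  noise, at the cost of slightly noisier TC values).
- No multi-frame enhanced DICOM, no DICOM writing, no scanner-specific
  Dixon phase correction, no inter-/intra-rater machinery.
- The SAT-from-contour auto-assignment is a convenience, not a validated
  rule; depot assignment is intended to come from explicit seeds.
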