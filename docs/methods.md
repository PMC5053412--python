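# Methods

`ropscreen` screens single posterior-pole fundus photographs of premature
infants for aggressive posterior retinopathy of prematurity (APROP), a
rapid-onset form of ROP whose hallmark is tortuous, heavily branching
vessels close to the optic disc (OD).  The pipeline quantifies exactly
those two signs — a tortuosity index `T` and a vessel-segment count `S` —
inside OD-anchored diagnostic regions, and classifies each eye with an
equal-prior linear discriminant plus a precautionary two-region fusion
rule.  This note records the model, its assumptions, the tunable
parameters, and the design decisions taken where the procedure was
genuinely open.

## Pipeline model

1. **Eye mask.** The mean-channel intensity is contrast-stretched between
   its 1st and 99th percentiles and thresholded (Otsu by default,
   override available); holes are filled and the largest component kept.
   The saturated border ring — the pixel population at or above the
   99th-percentile stretch limit — is removed explicitly, followed by a
   5-px safety erosion (`eye_margin`).  Removing the saturated population
   rather than relying on a large erosion is what makes the mask
   independent of the (configurable) ring width.
2. **OD geometry.** Two manually annotated major-axis endpoints define
   the OD circle: centroid = midpoint, radius = half the endpoint
   distance.  The OD is not truly circular; the circle is an exclusion
   zone, not a shape model.
3. **Channel selection.** Over eye-mask pixels only, channels with mean
   intensity at or below 64 (the 25th percentile of the 8-bit range) are
   discarded as underexposed; among survivors the least-variance (most
   uniformly illuminated) channel is used.  Ties break green, blue, red.
   If no channel survives, the brightest is used and a warning logged.
4. **Segmentation** (three interchangeable backends, below).
5. **Skeleton analysis.** Thinning to unit width; branch points
   (Rutovitz crossing number >= 3) and end points (exactly one
   8-neighbor); branch-point deletion splits the skeleton into ordered
   pixel chains; terminal spurs shorter than `spur_len` = 10 px are
   removed, the skeleton re-thinned and critical points recomputed
   (single pass by default, `prune_passes` configurable; the no-short-
   terminal-segment invariant is guaranteed only at fixpoint).  An area
   threshold (`area_min` = 20 px) removes short fragments; it is applied
   to the matched-filter and scale-space networks by default and is
   optional for morphology, whose entropy threshold already suppresses
   weak structure.
6. **Features.** Regions in OD-radius units: DR1 = disk of 4 r, EDR1 =
   disk of 6 r, DR2 = annulus 4-8 r, all minus the OD, intersected with
   the eye mask.  Vessels arch at roughly 4 r, and arcade curvature at
   the DR1 boundary would masquerade as pathology; EDR1 absorbs it.  A
   segment belongs to a region iff at least half its chain pixels lie
   inside (ties count as inside).  Per segment, tortuosity = arc length /
   chord length, where arc length is the chain sum of unit orthogonal and
   sqrt(2) diagonal steps; per region, `T` = mean of the segment
   tortuosities at or above their 75th percentile (numpy linear
   interpolation), `S` = number of assigned segments.  DR2 features are
   computed and reported but never classified — peripheral arborization
   is observational in this design.
7. **Classification.** A two-class pooled-covariance linear discriminant
   with equal priors and 0/1 cost on (T, S), one per region (DR1, EDR1),
   evaluated by leave-one-out cross-validation; features are z-scored
   from the training fold only (T and S differ by orders of magnitude;
   LDA is affine-equivariant so this affects conditioning, not exact
   decisions).  The fused label is healthy only if both regions are
   healthy.  The OR rule can only add positives: it trades false
   positives for sensitivity, the right asymmetry for a screening tool.

## Segmentation backends

**Morphology + co-occurrence entropy (default).**  The selected channel
is blurred by the mean of twelve uniform 9-px line-kernel convolutions
(one per 15 degrees); `blurred - channel`, clipped at zero, turns dark
vessels into a bright residue, rescaled to [0, 255] using the eye-mask
maximum (the enormous residues at the field border and OD rim would
otherwise compress the vessel signal).  The threshold maximizes the sum
of the second-order entropies of the background quadrant `C[0..t, 0..t]`
and foreground quadrant `C[t+1.., t+1..]` of the 256x256 symmetric gray
level co-occurrence matrix (horizontal + vertical unit offsets, pairs
with both pixels in the eye mask, log base 2, first maximum on ties).
The implementation uses a cumulative-sum identity
(`H = log2 S - L/S` with `L = sum c*log2 c`) and is tested against
exhaustive per-threshold maximization.

**Matched filter.**  Twelve zero-mean kernels with Gaussian cross-profile
`-exp(-v^2/2 sigma^2)` (sigma = 2 px, axis length 9 px — the classic
defaults for this filter family; both configurable), at 15-degree steps
measured from the vertical image axis, the orientation vessels are
assumed to align with.  Kernels are recomputed analytically per angle
(not resampled), so each is zero-mean to machine precision.  Per pixel
only the maximum response is kept; Otsu's threshold over the eye mask
binarizes it.  A constant response image yields an empty network, logged,
not an error.

**Scale space.**  For window sizes 3, 5, 7, 9, 11 (sigma = s/6 so the
Gaussian truncates at the window): blur, Laplacian response clipped at
zero (dark lines respond positively; the negative side lobes of bright
structures must not enter the threshold statistics), adaptive 3x3 median
(applied only where a pixel deviates from its local median by more than
three masked MADs — an impulse-detection criterion, window and rule
configurable), Otsu, and removal of islands below `island_min` = 20 px.
A pixel is vessel iff foreground at >= 3 of the 5 scales; the voting
suppresses capillaries, impulse noise and choroidal texture that appear
at only one or two scales.

**OD-boundary halo.**  Every linear enhancement responds to the bright
disc's rim as strongly as to a vessel.  The procedure omits the OD
*boundary* from feature computation; all three backends therefore exclude
the OD disk dilated by `od_halo` = 5 px (about half the 9-px enhancement
window).  Region masks still subtract only the plain OD disk.

## Tortuosity index details

The index is arc/chord per segment, which is >= 1 with equality exactly
for collinear chains.  (The index's other published rendering — pixel
count over squared chord — is dimensionally inconsistent with the claim
that every vessel scores above 1; it is available as
`mode="literal"` for comparison.)  Closed loops (coincident endpoints)
score the configurable `loop_cap` = 10: loops are strong tortuosity
signals and must stay in the set, but their ratio is infinite.  The cap
also clamps open segments: a segment that curls back to nearly its own
start is the open limit of a loop, and an uncapped ratio (observed up to
~33 on phantoms) would let a single segment dominate the top-quartile
mean.

Chain-code arc length carries an orientation-dependent positive bias of
up to ~8% (a digital straight line at 22.5 degrees measures 1.082x its
true length).  This bias is common to every segment and cancels in
class comparisons; where a test needs absolute digital length (the
phantom raster-vs-analytic invariant) the corrected chain-code estimator
(0.980 per orthogonal step, 1.406 per diagonal, -0.091 per corner) is
used instead.

## Skeleton conventions

8-connectivity throughout.  A branch point is a pixel with Rutovitz
crossing number (0-to-1 transitions around its 8-ring) of at least 3 —
the literal meaning of "more than one route to take".  A raw >= 3
neighbor count misreads the pixel under a T-bar junction (four
neighbors, three mutually adjacent) as a junction, which fragments spurs
and breaks pruning.  After branch-point deletion, emergent junction
pixels (a deleted junction can promote its neighbor into one) are peeled
iteratively so arms always separate; single-pixel leftovers between
adjacent junctions are debris and dropped (segments have >= 2 pixels).
Isolated short components are never pruned (the spur rule concerns
terminal branches off a junction); the area threshold handles them.

## The phantom generator

Ground truth for every stage comes from synthetic fundus phantoms:
a circular illuminated field (outside ~5 gray), a saturated ring
(`ring_width` = 10 px at 255, saturation clips noise), a bright OD disk,
and dark vessels — Gaussian cross-profile dips of 60 gray levels on a
reddish background (RGB ~ 140/70/35), 60% depth in green — plus
additive Gaussian sensor noise (`noise_sd` = 1.0 gray level, the order
of a device-processed 8-bit still).

Centerlines are radial trunks from the OD rim perturbed by a sinusoid
normal to the path: amplitude (`tortuosity_amp`, px) and frequency
(`tortuosity_freq`, cycles per 100 px) control tortuosity with a
closed-form arc/chord oracle, computed on the continuous curve before
rasterization so raster quantization cannot contaminate it.  Branches
spawn along the path with probability `branch_prob` per unit arc length,
deflect 20-50 degrees, cover 30-70% of the remaining radial budget, and
recurse at most two generations — bounds chosen so a phantom holds tens
of segments, like a real fundus, rather than an unbounded cascade.

Class presets (calibration choices; the clinical literature describes
APROP geometry only qualitatively):

| parameter        | healthy | aprop | rationale                          |
|------------------|---------|-------|------------------------------------|
| tortuosity_amp   | 1 px    | 5 px  | near-straight vs clearly tortuous  |
| tortuosity_freq  | 1.5     | 2.5   | gentler vs tighter wiggles         |
| branch_prob      | 0.01/px | 0.04/px | sparse vs excessive branching    |
| n_trunks         | 5       | 6     | slightly denser posterior tree     |
| vessel_width     | 3 px    | 4 px  | dilation accompanies the disease   |
| vascular_extent  | 9 r     | 6 r   | healthy may reach the periphery; the disease concentrates posteriorly |

What the phantoms do **not** model: choroidal texture, illumination
gradients, laser scars, vessel-width variation along a vessel, crossings
with realistic contrast, or any longitudinal change.  Passing tests
therefore demonstrate that the pipeline measures what the generator
encodes (tortuosity ordering, branching ordering, class separation under
these presets) — not clinical accuracy on real RetCam images, for which
the published operating figures cannot be reproduced here.

## Numerical choices and degenerate inputs

- Otsu thresholds always computed over masked pixels, 256-bin histogram.
- Entropy threshold: `0 * log 0 := 0`; candidate thresholds with an empty
  quadrant are invalid; a constant image raises a degenerate-input error.
- Constant matched-filter/scale-space responses give empty networks.
- Empty regions give `T = NaN`; such images are excluded from that
  region's classifier fit and fall back to the suspect (APROP) label at
  fusion — the conservative direction for screening.
- A LOOCV fold whose training data collapses to one class counts the
  held-out sample as an error (logged).
- Singular pooled covariance (e.g. one sample per class) receives a ridge
  of `1e-6 * trace` on the diagonal, logged via `regularized_`.
- All randomness flows through `numpy.random.default_rng` seeds; cohort
  per-image seeds spawn from the master seed, so every run is
  bit-reproducible.

## Problem sizes used by the test suite

Unit tests run on 320-px phantoms; cohort-level checks use the package
defaults (640-px images, 15 healthy + 21 APROP for separation, 10 + 10
with equalized presets for the null, 20 phantoms per level for the
amplitude grid {0, 2, 4, 6} and branching grid {0.005, 0.02, 0.04}).
The branching grid is evaluated at the posterior-concentration geometry
(vascular extent 6 OD radii, the APROP preset's): at longer extents a
0.04/px branch rate produces a vessel density (hundreds of true
segments) at which overlapping vessels merge in any segmentation and
the measured count saturates — the upper end of the measurable regime.

## Known limitations

- The fixed 9-px blur window and 10-px spur threshold are pixel-unit
  parameters; the feature definitions are scale-free (OD-relative
  regions, ratio-valued T) but the segmentation operating point is not,
  so acquisitions at very different resolutions should rescale
  `blur_length`, `spur_len` and `area_min`.
- The entropy threshold adapts to the noise floor; at noise levels well
  above ~2 gray it retains speckle that inflates S (the area threshold
  mitigates this for the matched-filter and scale-space backends).
- Chain-code tortuosity has a small orientation-dependent bias (above);
  it cancels between classes but adds variance for short segments.
- The two-point (T, S) feature vector ignores vessel width/dilation,
  an acknowledged clinical sign, by design.
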