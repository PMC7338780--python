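# Methods

## The counting model

Alexander staining gives a colour-coded readout of pollen viability: viable
grains (intact cytoplasm) stain dark blue/purple, aborted grains stain light
blue, and the slide background stays pale. Decomposed into RGB channels,
both stain classes absorb strongly in red, while only the dark-blue class
absorbs strongly in green. Counting dark particles in the red channel
therefore estimates the total grain number *t*, counting dark particles in
the green channel estimates the viable number *v*, and percent viability is

    PV = 100 · v / t.

PV is undefined (not zero) when *t* = 0, and can exceed 100% when the red
channel undercounts or the green channel overcounts — a real failure mode of
weakly stained slides that the package reports with a warning rather than
hiding.

Particles are accepted by closed size/circularity windows. Circularity is
4π·area/perimeter², computed from the pixel count and the weighted
boundary-step perimeter estimator of `skimage.measure.regionprops`
(straight steps 1, diagonal steps √2, corner-corrected) and clipped at 1.0,
since the discrete estimator can slightly undershoot the true contour length
on small round objects. The estimator choice is part of the method
definition: circularity thresholds are only meaningful for a fixed perimeter
convention. Rasterized discs of radius ≥ 10 px measure circularity
0.94–0.98 under it; ellipses of eccentricity 0.6 about 0.96.

## Pipeline stages and numerical choices

**Background subtraction.** Rolling-ball per channel on the inverted
intensities (grains are dark on a pale slide). Default radius 50 px —
comfortably above the 10–17 px radius of grains in the 100–900 px² range, so
grains are not absorbed into the background estimate. For radii above ~12 px
the plane is resized down by ~radius/12 (edge-padded bilinear), the ball
runs at the reduced radius and the background is upscaled back; the
approximation error is far below the 8-bit noise floor. Only the spatially
varying part of the estimate (around its median) is subtracted, so a
background-flat image passes through nearly unchanged while gradients are
flattened.

**Thresholding.** The default rule marks pixels at least 25% darker than
the modal background intensity (the pale mode always dominates a countable
slide, which the generator's ≤ 30% packing guard mirrors). Classical
histogram splitters (isodata, Otsu, mean) are selectable by name, but are
not the default for a structural reason: the channel histograms are
trimodal (dark stain, light stain, background), and a two-class splitter
wanders between the stain modes as their proportions shift — on
viable-heavy images it lands on the light-blue red-channel mode and clips
non-viable grains out of the total; on all-non-viable images it pulls
light-blue grains into the green channel and inflates viability. The
relative rule pins the criterion to the one stable histogram feature.
Constant channels yield an empty mask (degenerate, no contrast).

**Mask refinement.** Dilate ×1, fill holes, erode ×1 with a 3×3 square
element: closes pale grain centres and ragged outlines; on convex shapes
dilation and erosion are near-inverse, preserving areas to within a few
percent.

**Watershed.** Euclidean distance transform of the foreground, smoothed
with a σ = 0.7 px Gaussian; seeds are its regional maxima with prominence
> 0.5 px (h-maxima), seeds closer than 5 px merged; flooding on the negated
smoothed map within the mask. The prominence criterion (rather than plain
local maxima with a minimum separation) is what keeps non-grain shapes
whole: an elongated object's distance ridge is near-flat, with shallow
long-wavelength oscillations that a separation rule happily seeds many
times, whereas two overlapping grains always meet in a neck whose distance
value dips well below both lobes. On seeded geometry batteries the policy
splits 0/200 isolated grains, 199/200 touching pairs and 199/200
three-grain chains correctly.

**Edge particles** are counted by default (a configurable flag excludes
them): silently dropping frame-cut grains would bias dense images.
Labelling uses 8-connectivity (configurable to 4).

## Scenario evaluation

`run_scenarios` computes one result per image × scenario. All stages
before filtering are scenario-independent, so each image is segmented and
measured once and every scenario re-filters the measured particles —
identical results to running the chain per pair, 7× cheaper.

Correlations against manual counts are Pearson product-moment coefficients
(two-sided p from the t-transform with n−2 df), requiring ≥ 3 pairs and
nonzero variance; images with undefined automatic PV are excluded pairwise
from the viability correlation and counted. Images with PV > 100% are
retained by default (they carry real signal about miscounting), with a flag
to exclude them. The best scenario maximizes the count correlation, with
ties broken by the viability correlation and then lexicographically by
name — counts are the primary evidence that the windows capture the grains;
the name rule makes selection deterministic when scenarios are genuinely
equivalent (e.g. when every grain's circularity clears even the tightest
window, S1, S3 and S5 produce identical counts).

Group summaries use the sample standard deviation (n−1).

## The synthetic scene generator

The generator renders exactly the features the pipeline exploits, with
exact per-grain ground truth standing in for manual counts:

* colour model (mean RGB before jitter and noise): viable (70, 50, 120),
  non-viable (150, 190, 220), background (235, 225, 230), debris
  (60, 60, 70) — encoding "dark blue vs light blue on a pale slide" such
  that red sees both classes and green separates them;
* elliptical grains, areas sampled from a configurable window (default
  150–850 px², safely inside the 100–900 px² counting window even after
  rasterization; rasterized areas stay within ±10 px² of the draw),
  eccentricity ≤ 0.6 (circularity ≥ ~0.9);
* clusters: a configurable fraction of grains is attached to an existing
  grain at 0.85–0.98 × the sum of their radii — rigid grains interpenetrate
  only slightly in projection, so the pair merges into one blob while each
  grain keeps a distinct distance-map lobe (separation always exceeds
  1.2 × the mean radius);
* debris: sub-threshold dark specks (10–60 px²) and oversized spiky blobs
  (area 1100–2300 px², circularity ~0.15) that every catalogued filter must
  reject on size and shape;
* Gaussian sensor noise (default sd 2 intensity levels), optional linear
  illumination gradient (±25 levels across the width), per-grain colour
  jitter (sd 5);
* a packing guard rejects scenes whose grains would cover > 30% of the
  image, keeping the "background is the dominant mode" premise true.

A single seed drives one RNG whose stream order is documented
(classes, geometry, placement, jitter, debris, noise), so scenes are
bit-reproducible. The default scene is 1024 × 768 px with 40 viable + 10
non-viable grains (80% viability); benchmark sets draw per-image totals
from 20–120 and viabilities from 10–95%, with 10% of grains in the
[100, 200) px² band — the band that distinguishes the 100–900 size window
from the 200–900 one. Bulk recovery runs use 640 × 480 scenes with 25
grains; the 31-image benchmark uses the full default scene size.

### What the generator does not model

No point-spread blur, chromatic aberration, focal-plane variation,
partially stained grains, or textured grain walls; debris is never in the
grain size-and-shape window simultaneously. Passing tests therefore show
that the algorithm chain is correct under the stated stain-contrast model,
not that it handles every real-world slide; on real images the practical
failure modes remain weak staining (addressed by the contrast-enhancement
rescue step, off by default because over-stretching inflates the viable
count) and heavy clumping, which no watershed fully resolves.

## Known limitations

* Thin fibrous debris (hairs, fibres) is fundamentally ambiguous for any
  distance-transform watershed: a fibre fragments into grain-sized pieces
  that can enter the count. The generator's large debris is compact and
  spiky instead; fibres on real slides should be kept off the slide (or
  excluded by eye).
* Areas are reported in raw pixel²; no physical calibration (µm²) is
  attempted, so scenario windows must be re-derived when magnification
  changes.
* The viability discrimination is binary; stain intensity between the two
  classes (partially viable grains) is not quantified.
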