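# Methods

## Scope and design

`pillchroma` studies how imaging conditions move pill colours in CIE
L\*a\*b\* space and how that movement degrades recognition accuracy. The
experimental unit is one medication (19 classes); the design is fully
within-subject: every medication is imaged under one reference condition
(black background, flash off, EV 0) and all 12 cells of the
background (2) × flash (2) × EV (3) factorial. All analyses treat the
medication as the repeated-measures subject.

## Synthetic scene model

The renderer is deliberately minimal: it reproduces the qualitative
dependencies of photographed pill colour on background, flash and exposure
without attempting physically based rendering, lens distortion or a real
camera's white-balance/demosaicing pipeline.

For a pill with base surface colour `c ∈ [0,1]³` on a field of level `g`
(black 0.02, white 0.98):

```
pill radiance  = c · auto_gain(g),  auto_gain(g) = 1 − κ·(g − 0.02)
flash on       : whole scene ×1.15, plus a Gaussian specular highlight
                 (amplitude 0.35, σ = 0.45·pill radius, offset from centre)
exposure       : whole scene ×2^EV   (photographic stops)
sensor noise   : + N(0, σ/255) per channel, σ = 2.0 counts
quantisation   : clip to [0,1], round to 8 bits
```

The auto-exposure term emulates a camera metering the whole frame: a white
field drives the meter down and darkens the pill relative to the black-field
rendering (κ = 0.25, so the white-background pill gain is 0.76). The
coupling is anchored at the *reference* background level, which makes the
reference condition an identity render: with noise disabled, the mean pill
RGB equals the ground-truth surface colour to within quantisation. This
anchoring is what lets every ΔE be interpreted as distance *from truth*.

Pill geometry: seven convex silhouettes (disk, ellipse, two stadium
elongations, regular triangle/pentagon, diamond) at a jittered 35 ± 5 % of
canvas area (clipped to [20 %, 60 %]), random rotation and small centre
jitter. Roughly half the pills carry an imprint, rendered as a thin embossed
bar at 70 % brightness covering ≈1.2 % of the pill; the ground-truth colour
folds the imprint into the area-weighted mean so the identity property holds
at any size. Every image derives its own child seed from
(experiment seed, label, condition, replicate) via `SeedSequence`, so
datasets are bit-reproducible and individual frames can be regenerated in
isolation.

What the generator does **not** emulate: specular materials and gloss
variation between dosage forms, shadows, perspective and defocus, texture,
debossed vs printed imprints, and the spatially varying illumination of a
real light box. Passing tests therefore demonstrate the *pipeline logic* —
segmentation, colorimetry, inference — under controlled colour shifts, not
performance on real photographs.

## Segmentation

The extraction chain is grayscale (BT.601 luma) → Gaussian blur (σ = 2 px)
→ global Otsu threshold with polarity chosen from border statistics (the
frame border is assumed background) → Canny (8-bit thresholds 50/150,
σ = 1) on the blurred grayscale → morphological closing (disk r = 2) →
hole-filling of the outer contour → largest connected component → bitwise
mask → square crop (pad 4 px, short side expanded symmetrically, window
shifted inward at borders). Because the published step order is ambiguous
about the Canny input, a config switch (`canny_source`) also supports
running Canny on the thresholded mask.

Fallback policy: if the contour route finds no closed outline or yields an
implausible area fraction (outside 0.5–95 % of the frame), the thresholded
mask is used and the fallback is logged per condition. If both routes fail —
typically a constant, fully clipped frame such as a white pill on a white
background at EV +2 — the caller receives a `SegmentationError` naming the
stage. The orchestrator then falls back to the full-frame mean colour (and
scores the image as a recognition miss) so that the repeated-measures design
stays complete; these frames are counted in the segmentation log.

## Colorimetry

Channels are normalised to [0,1] and mapped by the fixed matrix

```
X = 0.4303·R + 0.3416·G + 0.1784·B
Y = 0.2219·R + 0.7068·G + 0.0713·B
Z = 0.0202·R + 0.1296·G + 0.9393·B
```

then to L\*a\*b\* with the CIE 1976 equations and
f(q) = q^⅓ (q > 0.008856), 7.787·q + 16/116 otherwise; the two branches
agree at the knee to < 1e-4. This matrix is not the sRGB/D65 standard
matrix; it is implemented verbatim as the study's conversion. Consequently
the default reference white is *anchored*: (Xn, Yn, Zn) =
image of RGB white = (0.9503, 1.0000, 1.0891). That choice makes white map
exactly to L\* = 100 and keeps L\* within [0, 100] over the whole in-gamut
cube (the middle matrix row sums to 1); a D65 white point is available via
config. ΔE is the Euclidean ΔE\*ab; more recent formulas (ΔE94, ΔE2000) are
out of scope.

Granularity: the ROI is reduced to its mean RGB first, then converted —
matching the mean-channel workflow of ImageJ-style RGB analysis — rather
than averaging per-pixel ΔE. Per pill, the reference anchor is the mean Lab
over reference replicates; ΔE is computed per condition replicate against
that anchor and averaged, giving one value per (pill, condition) cell. The
phrase "subtracting colour distances" admits another reading (difference of
two distances); this package implements the distance between the two
colours, which is the quantity a colour-difference metric defines.

## Surrogate recognizer

The study-scale CNN is replaced by a transparent classifier so the
accuracy-versus-ΔE analysis is runnable on one CPU: 11 features per ROI
(mean L\*, a\*, b\*; area fraction; aspect ratio; circularity 4πA/P² with a
Crofton perimeter, which is stable under rescaling; four log-compressed Hu
moments; an imprint score = fraction of pill pixels below 80 % of the
median pill luminance), standardized per dimension over the training set,
nearest-class-mean with Euclidean distance and ties broken toward the lower
label. Training uses reference-condition images only, mirroring the
reference-trained / real-world-tested protocol. Any object implementing
`predict_topk` can be plugged into the evaluation, so a CNN backend can
replace the surrogate without touching the metrics. Absolute accuracies of
a GPU-trained network on real photographs are explicitly not reproduced;
the surrogate exists to expose the *direction* of the condition effect.

## Statistics

* Summaries: per-condition mean and sample SD (n−1) of ΔE over medications;
  a single-record condition reports SD 0 by convention.
* Three-way RM-ANOVA: univariate within-subject F tests (statsmodels
  `AnovaRM`) for the three main effects and all interactions, α = .05.
  Sphericity is uncorrected by default to match the study protocol; a
  Greenhouse–Geisser option multiplies both degrees of freedom by the
  ε estimated from the effect's subject×cell matrix. A response with zero
  variance across cells within every subject yields the null report
  (F = 0, p = 1) rather than a 0/0 artifact.
* Stratified analysis: within each background×flash stratum, a one-way
  RM-ANOVA over EV (all three levels required), then paired t tests for the
  three EV pairs with Bonferroni factor 3 (adjusted p = min(1, 3p)). The
  stratified model assumes medication is the subject and EV the sole within
  factor.
* Association: Spearman rank correlation between per-condition mean ΔE and
  top-k accuracy across the 12 conditions; constant inputs are reported as
  ρ = 0 with a degeneracy flag; condition pairs ordered against the inverse
  relation are listed as violations.
* Calibration: seeded Monte-Carlo helpers simulate the 19-subject design
  (subject SD 1, noise SD 1) and report per-effect rejection rates — the
  type-I rate under the null and power under an injected EV main effect
  whose across-level SD is twice the noise SD.

## Problem sizes and numerical choices

Default experiment size is 19 pills × 13 condition sets × 2 replicates
(494 images at 128×128), which runs the full pipeline in a few seconds;
`n_per_cell` and canvas size scale it up. The test suite's calibration uses
1,000 null replicates and 200 power replicates; the end-to-end direction
check averages the Spearman coefficient over 5 experiment seeds. Colorimetric
algebra is double precision with 1e-9 tolerances on identities; the L\*
range scan uses a step-3 lattice of the RGB cube (~636k points, extremes
attained at the included corners). All randomness flows through
`numpy.random.Generator` seeded per call; reruns are byte-identical.

## Known limitations

* The rendering model is phenomenological; its auto-exposure and flash
  parameters are plausible, not fitted to any camera.
* ΔE magnitudes depend on the synthetic gamuts and gains, so only their
  ordering across conditions — not their absolute values — should be
  compared with measurements on real photographs.
* The surrogate classifier's absolute accuracy is not meaningful outside
  this benchmark; shape features are nearly condition-invariant, so its
  condition sensitivity is driven almost entirely by colour, which is the
  point of the analysis but understates failure modes a CNN might show.
* One-pill-per-frame scenes only; multi-pill detection is out of scope.
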