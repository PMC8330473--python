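# Methods

This note records the models, conventions and deliberate simplifications
behind `patchcamo`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Colour pipeline

All statistics are computed in CIELab after conversion; nothing is ever
averaged in gamma-encoded RGB. The pipeline is display-referred:

1. **Decode**: a pure power law, `linear = (v/255)^(1/0.42)`. The 0.42
   exponent is the presentation transform used for the online stimuli;
   its inverse is the decode. The piecewise sRGB EOTF is deliberately
   *not* used — the presentation images are defined by the plain power
   transform, and using the same transform both ways keeps
   encode/decode mutually inverse (verified exactly on all 256 levels).
2. **Linear RGB → XYZ**: the fixed sRGB/D65 primary matrix. Real
   calibrated workflows derive XYZ from camera-specific cone-catch
   models fitted to colour-chart photographs; that calibration is out of
   scope here, so absolute Lab coordinates differ from a calibrated
   pipeline. Every quantity the analyses consume is a colour
   *difference or mean within this one pipeline*, which is unaffected by
   that offset in practice; the acceptance checks are accordingly
   property-based (recovery, ordering, calibration), not absolute colour
   reproduction.
3. **XYZ → Lab**: CIE 1976 with the cube-root/linear-segment function,
   D65 white (Y-normalised), chosen because the imagery this emulates is
   daylight field photography assessed by human observers. The inverse
   map exists purely for round-trip testing.

**CIEDE2000** is implemented in full (G chroma rescaling, atan2 hue
angles mapped to [0°, 360°), the CIE branch rules for Δh′ and the mean
hue, the T term and the blue-region rotation term R_T). It reproduces
the published 34-pair verification suite to better than 1e-4 and matches
scikit-image's independent implementation to 1e-9 on random pairs. One
caveat uncovered in testing: the formula itself is discontinuous where
the two hue angles are exactly 180° apart (jumps of order 0.01); the
continuity property is therefore asserted everywhere except a 1° band
around antipodal hue pairs.

## Synthetic scenes

A scene is a per-pixel Lab image plus a ground-truth microhabitat label
map. Labels come from one Gaussian noise field per microhabitat,
smoothed with a Gaussian kernel of σ = patch_scale/2, standardised, and
combined by per-pixel argmax. Weight-derived offsets are added to the
standardised fields; they are solved numerically (Gauss–Hermite
quadrature + least squares on the K−1 free offsets) so the expected
areal fraction of each habitat equals its requested weight — exact for
the marginal distribution, so empirical fractions match within sampling
error. Pixel colours are drawn independently per channel around each
habitat's mean Lab with its SDs.

The smoothed-field construction (rather than, say, Voronoi cells) gives
continuous control of patch scale and naturally intermingled,
heavy-tailed patch-size distributions, which is the regime the patch
statistics are about. An optional `local_bias` adds a Gaussian bump to
one habitat's field around the scene centre: it emulates a target site
sitting in a locally distinctive patch, which is what makes the *near
zone* around a centred target genuinely different from the whole-scene
average (without it the two contrast predictors are nearly collinear
and carry the same information).

What the generator does **not** emulate: spatial texture within a
habitat (pixel colours are iid given the label), occlusion, topography,
illumination gradients, and the spatial autocorrelation of real
vegetation colour. Tests passing on these scenes therefore demonstrate
that the *algorithms* behave as specified under known ground truth, not
that real photographs would segment at the same accuracy.

The default target is a stylised sitting-hare silhouette with the
40 cm × 26 cm aspect of the physical models, cropped to its bounding box
so the rescaled mask height is exactly `round(height_mm · px/mm)`
(320 px at 0.8 px/mm, 120 px at 0.3 px/mm).

## Scene analysis

**Ranked smoothing.** The published analysis smooths with a
receptor-noise-limited ranked filter parameterised by (chromatic Weber
fraction 0.05, luminance Weber fraction 0.1, kernel radius 3, falloff 2,
3 iterations); its exact semantics are not public. The implementation
here is a documented interpretation keyed to those five parameters: for
each pixel, neighbours within the kernel radius whose colour difference
from the centre falls below a discriminability gate contribute to a
channelwise median replacing the centre. The gate is
`weber × 100 × threshold_scale × (1 − r/R)^falloff`, applied to |ΔL| for
luminance and to Euclidean (a, b) distance for chroma; `threshold_scale`
defaults to 2.0, chosen so the default parameters visibly flatten
sub-threshold speckle on the synthetic fixtures while leaving
high-contrast boundaries untouched (both properties are tests). The
filter sits behind a plain function interface so a faithful port of the
original tool could be swapped in.

**Segmentation** is a diagonal-covariance Gaussian naive Bayes
classifier per habitat (means and SDs from the selected colour groups,
SD floor 1e-6, uniform priors by default — the original tool does not
state its priors). Ties resolve to the lowest habitat index. Excluded
pixels (target + exclusion ring) carry the sentinel label −1.

**Particle analysis** is connected-component labelling per habitat;
8-connectivity by default (common particle-analysis practice),
4-connectivity available and used in the checkerboard test.

**Near zone**: dilate(target, exclusion+band) minus dilate(target,
exclusion), with a square (Chebyshev) structuring element by default —
deterministic and closed-form testable (a 10×10 square target with
exclusion 1 and band 3 yields 18² − 12² = 180 px); a Euclidean disc is
available. The zone is clipped at image borders and the realised area is
whatever the mask reports; the band width is one target height, and the
exclusion ring (4 px at 0.8 px/mm, 2 px at 0.3 px/mm in the emulated
protocol) keeps stray target pixels out of the background statistics.

**Contrast predictors**: ΔE_near is CIEDE2000 between the target colour
and the mean Lab of the near zone; ΔE_whole uses the whole scene minus
target, exclusion ring and any scene-level exclusions.

## Detection-trial simulator

Proportional hazards are imposed directly on the transformed scale
u = 1 − d/d_max, because that is the scale the models are fitted on; no
claim is made about hazards on raw metres. Event draws are exponential
with rate `baseline_hazard · exp(xβ + b_subject + b_position)`; draws
beyond the position's maximum u (= 1 − d_min/d_max) are censored and the
response records the closest approach. Random effects are normal on the
log-hazard scale, matching mixed-effects hazards convention. A single
seed expands into per-component substreams (layout, distances, random
effects, events) so adding a stage never perturbs earlier streams.

Defaults mirror the emulated field design: 39 subjects × 20 positions
(780 presentations), generalist-vs-specialist log hazard ratio log 0.5,
frailty SDs 0.2, maximum viewing distances uniform on 30–90 m (mean
60 m), minimum approach 2–10 m, and baseline hazard 4.0, chosen so
roughly one presentation in ten is censored — the missed-target rate of
the emulated study. The exponential baseline is a simulator convention;
the true distributional form of field detection distances is unknown.

## Survival modelling

Fixed effects maximise the Cox partial likelihood with Efron tie
handling (field distances are rangefinder-quantised, so ties are
expected; Breslow is available). The no-ties fast path computes the
score and information through cumulative risk-set sums; correctness is
anchored by agreement with lifelines to 1e-6 in β on shared datasets
(untied, tied and stratified).

Random effects use penalised partial likelihood: Newton on (β, b) with
penalty bᵀD⁻¹b/2, and variance estimation by maximising the Laplace
approximation of the integrated likelihood,
`l_int(σ²) = l_pen(β̂, b̂) − ½ log det(I + D·H_bb)`, over log-variances
with Nelder–Mead (loose tolerances — the profile is flat and the
estimator contract is behavioural: CI coverage and parameter recovery,
not numerical identity with any particular mixed-model package).
Standard errors come from the inverse penalised information, CIs are
Wald on the log-hazard scale.

AIC uses the integrated log-likelihood with effective parameter count
p_fixed + (one variance per frailty term); ladders only ever compare
fits sharing the same response data and random-effect structure, and
flag ΔAIC > 6 as substantial. Likelihood-ratio tests require nesting and
use the integrated log-likelihood when frailties are present.

The proportional-hazards check is a Grambsch–Therneau-style score test:
Schoenfeld residuals correlated with a transform of the event response
(identity by default, rank available), per-covariate χ²₁. Its size is
near nominal under PH and its power against a mid-search change of
effect exceeds 0.8 at n = 2000 (both simulated in the tests).

Online responses are stratified by crop size and by centre-distance
quartiles computed from the analysed dataset (per-dataset, not
per-crop-class — the alternative is a keyword away), with boundary ties
assigned to the lower quartile. Pairwise colour contrasts are reported
uncorrected; a Holm adjustment is available but not default, since the
emulated protocol reports planned comparisons without stating a
correction.

## End-to-end study and problem sizes

`study.simulate_study` runs the whole chain at a reduced photographic
scale chosen to keep a full study in a few seconds: 40 positions with
384×512 scenes at 0.16 px/mm (target 64 px tall), patch scale 8 px,
local-bias strength 2.0, 20 subjects (800 presentations), true ΔE_near
slope 0.06 on the log-hazard scale and baseline hazard 1.5 (≈10%
censoring). The acceptance computations use: 512² scenes (5 replicates)
for segmentation and patch statistics at the full 0.8 px/mm analysis
scale; 200 replicate studies for CI coverage; 400 replicates at 2000
presentations for null calibration — the null-calibration design uses a
high baseline hazard (near-complete detection) so the check isolates
estimator calibration from censoring.

## Known limitations

- The colour path is uncalibrated (no camera model); only within-pipeline
  differences are meaningful.
- The ranked filter is an interpretation of a tool whose reference
  semantics are unpublished; it is parameter-compatible, not
  bit-compatible.
- The Laplace/profile variance estimator can under-estimate very small
  frailty variances (it is truncated at e⁻¹² on the variance scale);
  coverage of fixed effects is the tested guarantee.
- Slide-set sampling is randomised greedy with restarts: uniform
  sampling over feasible assignments is approximate, and for
  deliberately impoverished databases the infeasibility diagnosis names
  the first unmet constraint found.
- Scenes are colour-only; pattern and luminance texture statistics are
  out of scope, as the targets this models are uniform.
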