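# Methods

## Problem and model

The package estimates the impurity content of corn during deep-bed drying
from top-view colour photographs of the grain surface. Three impurity
classes matter operationally: broken corncobs (compact, red-faced
rectangles), broken bracts (large, papery, pale husk sheets) and crushed
stones (small gray-blue fragments). The method is a classical
segmentation chain rather than a learned model: illumination
normalization (MSRCR), global binarization (Otsu), per-class colour
gating in HSV, class-specific mathematical morphology, and a
mass-weighted pixel count.

Underlying assumptions, made explicit:

* **Colour separability.** Each class occupies a closed hue/saturation
  band disjoint (in the h×s plane) from corn kernels: bract
  h ∈ [0.48, 0.6] × s ∈ [0.15, 0.25]; corncob [0.8, 1] × [0.06, 0.7];
  stone [0.55, 0.65] × [0.28, 1]. Hue is stored on the [0, 1] scale
  because every calibrated threshold uses it. Both interval ends are
  inclusive. The bract and stone hue ranges overlap but their saturation
  ranges are disjoint, so the band masks are provably exclusive; any
  overlap created later by morphology is resolved by class priority
  (stone > corncob > bract — stones have the tightest band and smallest
  area, so losing them costs most).
* **Size priors.** Bract fragments cover ≥ 4500 px and stones < 400 px at
  the working resolution (600 × 480). The boundary rules are implemented
  as ≥ 4500 and < 400; the exact boundary behaviour at equality is a
  convention, stated here and in the config, not a calibrated fact.
* **Illumination is multiplicative and smooth.** MSRCR's log-ratio
  cancels any per-pixel gain field that is approximately constant at the
  surround scales; this is what justifies enhancing before binarization.

## Pipeline structure and the HSV source

The Otsu foreground used in every AND step is computed on the
MSRCR-enhanced image: vignetted kernels otherwise drop out of the
foreground and take their impurities with them. The HSV values fed to the
band masks, however, are taken from the **original** image by default.
MSRCR operates per channel and then stretches each channel independently,
so it does not preserve hue; bands calibrated on unenhanced crops simply
do not apply after enhancement. Since hue and saturation in the hexcone
model are invariant under a multiplicative illumination change, the
original image is also the more stable colour source under the very
degradation MSRCR corrects. `ClassifierConfig.source` switches this.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| MSRCR scales σ | 15, 80, 250 | px | classic small/medium/large surround triple |
| weights | 1/3 each | — | no scale preferred a priori |
| α, β | 125, 46 | — | canonical colour-restoration constants |
| percentile clip | 1, 99 | % | self-calibrating output stretch |
| ε (log guard) | 1e-9 | intensity | see numerical choices |
| open radius (bract) | 3 | px | removes radicle specks (< ~100 px) without eroding sheets |
| close radius (corncob) | 5 | px | bridges 1–3 px surface cracks |
| dilate radius (stone) | 3 | px | re-grows band-mask dropouts before the AND restore |
| median window | 5×5 | px | drops isolated broken points, keeps 400 px objects |
| area rules | 4500 keep-≥ / 400 keep-< | px | class size priors |
| ρw, ρz | 7.31e-3, 1.05e-3 | mg/px | measured per-pixel mass densities; only the ratio matters |
| connectivity | 8 | — | diagonal-touching debris is one object |

The calibrated colour bands, area rules and densities are measured
quantities; the morphology radii are not, so the defaults
were chosen on the synthetic suite as the smallest kernels that close the
defects the generator produces, and all are exposed in the YAML config.

## Numerical choices

* **Otsu.** Computed on the 256-bin BT.601 luminance histogram, threshold
  t maximizing ω₀ω₁(μ₀−μ₁)² with foreground = gray > t. Ties are broken
  toward the smallest maximizing t for determinism. A single-level
  histogram raises a degenerate-input error rather than returning an
  arbitrary threshold. The implementation is vectorized; the test suite
  holds it to exact agreement with a plain exhaustive search on 1000
  random histograms.
* **ε = 1e-9 in the retinex logs.** ε exists only to make log(0) finite.
  The useful property of the whole MSRCR chain — invariance under a
  global illumination scale — degrades by O(ε/I); at ε = 1e-9 the float
  output of an image and its half-intensity copy agree to better than
  1e-6, which the tests assert. A large guard (e.g. ε = 1) would destroy
  that invariance for dark pixels, so it is deliberately tiny.
* **Constant-image convention.** The percentile stretch of a constant
  retinex field is undefined; it is defined to map to flat 128.
* **Boundary handling.** All convolutions and rank filters reflect at the
  border (edge sample duplicated); a zero-padded surround would create
  exactly the dark-frame artifact the enhancement is meant to remove.
* **0/0 conventions.** Precision, recall and F1 are 0 when their
  denominators vanish; impurity content with no classified pixels at all
  is an error, not a number.
* **Rounding.** Manifests report percentages to 2 decimals; dataclasses
  keep full precision.

## Synthetic scenes: what they emulate and what they do not

The generator renders 600 × 480 scenes: ~900 overlapping elliptical
kernels (h ∈ [0.08, 0.14]) over a dark inter-kernel background, with a
configurable mix of impurities whose per-pixel HSV is sampled strictly
inside each class band (0.01 margin, so 8-bit quantization cannot push a
truth pixel out of band). About a third of kernels get a pale radicle
tip painted inside the bract band — the documented false-positive source
that the bract area rule must reject. Stones are rendered inside a dark
"crevice" ring, emulating small debris settling between kernels; this is
also what makes the stone restoration step (dilate, then AND with the
binary mask) recover the stone without annexing adjacent corn
foreground. Degradations — a linear vignette ramp (darkest at top-left),
achromatic dust specks, additive Gaussian noise — are applied only after
the truth map and manifest are frozen.

What passing on these scenes shows: the stage contracts compose, the
band/area rules separate the classes they were designed for, enhancement
measurably rescues vignetted foreground, and the content estimator is
consistent with ground truth to well under 0.15 percentage points.

What it does not show: performance on real dryer imagery. Real corn has
continuous colour variation, moisture-dependent darkening, specular
highlights, kernel adhesion with soft shadows, and moldy/rotten kernels
whose colours approach the bract band — none of which the generator
models. The published field scores (per-class F1 in the 83–87% range)
are therefore not reproducible here; the synthetic scores are upper
bounds that validate the machinery, not the field accuracy.

## Problem sizes

The shipped checks use 20 clean and 20 degraded full-resolution scenes,
1000 random histograms for the Otsu cross-check and 10 random 120 × 160
images for the invariance check — sizes at which the whole suite and the
acceptance script each run in a couple of minutes on one core while
keeping the pooled pixel counts in the millions.

## Known limitations

* Fixed global thresholds: no per-batch recalibration of the HSV bands,
  although `channel_statistics` provides the calibration tool.
* The corncob pipeline has no area rule, so a large non-corn object that
  lands in its wide band (e.g. rot) would be accepted.
* White corncob-interior fragments are colour-indistinguishable from
  bracts and are labelled as bract (code 1); routing them to the corncob
  class would require shape context the colour model does not carry.
* Kernel adhesion is not split (no watershed); kernels are background to
  this task, so adhesion only matters through the Otsu mask.
* The luminance channel is excluded from classification by design, so
  classes separated only by brightness cannot be added without changing
  the model.
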