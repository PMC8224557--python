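# Methods

## Problem setting

Mandibular fractures appear on panoramic radiographs as thin dark crack
lines crossing the bright mandibular arc. The radiographs are globally dark
with strongly uneven illumination, which both hides cracks and confuses
detectors trained on them. `panofrac` implements the processing that
surrounds an external one-stage detector: photometric enhancement,
annotation augmentation, dataset assembly, post-processing of detector
output, and evaluation.

## Tone-mapping model

All enhancement operates on the luminance channel only (the radiographs are
grayscale) and is strictly pixel-wise in geometry, so box annotations are
valid on every enhanced variant.

**Gamma modulation.** `O = (I/255)^γ · 255` with the augmentation set
γ ∈ {1.0, 1/0.6, 1/0.3}. Exponents above 1 darken mid-tones; this keeps
crack/arc contrast while avoiding the saturation that brightening causes.
The dataset builder defaults to γ = 1/0.3, the strongest member of the set.

**SLAT.** Intensities are rescaled to `Ln ∈ [0, 100]` because the
luminance-level and visual-gamma fits are calibrated for adaptation under a
100 cd/m² surround. The adaptation luminance `Lan` is a Gaussian low-pass
of `Ln` (σ = `surround_scale` pixels, kernel truncated at 3σ, unit-sum,
reflective boundaries — reflection avoids dark halos at image borders).
Per pixel:

```
Lmin = 0.0212 + 0.0185 · Lan^1.0314
Lmax = 25.83  + 30.82  · Lan^0.6753          (Lmax > Lmin for all Lan ≥ 0)
γ    = 0.444  + 0.045  · ln(Lan + 0.6034)    (Bartelson–Breneman fit)
f    = |(Ln − Lmin)/(Lmax − Lmin)|^γ
```

then a global stretch `SLAT = Igain·f + Ioffset` with
`Igain = Rcs/(fmax − fmin)` and `Ioffset = −Rcs·fmin/(fmax − fmin)`,
`Rcs = 255` for 8-bit grayscale. With the negative offset the output spans
exactly `[0, Rcs]`; the positive-offset variant (which shifts the response
above black and clips at white) is kept behind
`SlatParams(corrected_offset_sign=False)` for comparison. `fmax`/`fmin` are
global over the image — the stretch is one affine map, not per-tile.
A flat input has no range to stretch (`fmax = fmin`); it maps to uniform
mid-gray `Rcs/2`.

**MLAT.** `MLAT = Σ wₙ·SLATₙ` over surround scales (15, 80, 250) px with
uniform weights by default (weights are validated to be non-negative and
sum to 1). Each `SLATₙ` is a complete pass including its own global
gain/offset, so every term individually spans `[0, Rcs]` and the convex
combination stays inside the hull of its terms. The single-scale default
for standalone SLAT is σ = 80, the middle multi-scale value. The small
scale preserves local boundary detail; the large scale renders global tone
and damps the noise amplification of the small one.

## Dataset assembly

Each source radiograph expands to three variants — gamma-modulated, SLAT,
MLAT — with byte-identical label files (nothing moves), so 360 sources
yield 1080 training images. Multi-box augmentation (on by default) emits
each fracture at three sizes: the reference box plus 0.7× and 1.6× copies
about the fixed center, in that deterministic order, sharing class and
fracture identity. Scaled boxes are intersected with the unit square and
the center re-derived from the clipped extent; a box that leaves the square
entirely is an error. Label coordinates are continuous center-based
normalized floats written at six decimals (round trips are lossless to
1e-6); pixel conversion is `x_px = cx·width` with no half-pixel offset.

## Detector-head arithmetic and post-processing

Each prediction scale is an `S×S` grid with `B = 3` anchors per cell and
`B·(5+C)` channels (4 box offsets + objectness + C class probabilities per
anchor): 33 channels for the six-class scheme, 21 for the two-class scheme;
at 608×608 input the strides 32/16/8 give 19-, 38- and 76-cell grids.
Scores compose as `confidence = Pr(fracture)·IOU` and
`class score = Pr(class|fracture)·confidence`. The raw head decode (anchor
offsets, activations) belongs to the external detector and is deliberately
not reimplemented; this module consumes decoded candidate boxes.

NMS is class-wise greedy: walk candidates in descending confidence (ties by
input order) and keep a box iff its IOU with every kept same-class box is
at or below the threshold (default 0.45, a standard detector default — the
pipeline that inspired it does not state one). Survivors therefore have
pairwise same-class IOU ≤ threshold, the top scorer of each class always
survives, and the operation is idempotent.

Test-time inference runs twice, on the SLAT and on the MLAT rendering of
the radiograph; the merge step rescales both sets from network-normalized
coordinates back to original pixel geometry (uniform non-letterboxed
stretch by default, letterboxing behind a flag) and unions them, tagged by
module. No cross-module suppression is applied by default — both modules'
boxes are meant to be shown side by side — but an optional cross-NMS
threshold is available.

## Evaluation

Matching is greedy in descending confidence: a prediction matches the
unmatched same-class truth with the highest IOU ≥ 0.5 (threshold
configurable). The default is *fracture-level* scoring: an extra prediction
overlapping an already-matched fracture is ignored rather than counted as a
false positive, because the clinical question is fractures found, not boxes
drawn, and a "misdetection" there means hitting something that is not a
fracture at all. Box-level scoring (duplicates are FP) and class-agnostic
matching (localization only) are flags. Precision, recall and F1 use the
defined-zero convention (0 on a zero denominator; F1 = 0 whenever TP = 0).
Accuracy is deliberately absent: true negatives are undefined when any
mandibular region could contain a fracture. The per-region report counts
diagnosed (matched) and undiagnosed (unmatched) truths per label; per-label
counts always sum to the global TP/FN.

## Synthetic data

The generator emulates exactly the properties the stack relies on: a dark
background (base level 40) with multiplicative vignette, a bright parabolic
jaw arc (peak 180) with Gaussian cross-profile, additive Gaussian noise
(σ = 6), and thin dark cracks (depth 90, ~1–2 px wide) crossing the arc
perpendicular to it. Default frame is 256×128 px — large enough for all six
region zones and the multi-scale surrounds, small enough that full-cohort
runs stay cheap. The six anatomic regions occupy fixed bands of the arc
parameter `|t|` (parasymphysis 0.02–0.18 near the midline out to condyle
0.88–0.98 at the tips, coronoid just inside), one zone per (region, side)
pair, so at most 12 fractures fit per image. "Linear" cracks are straight
polylines with sub-pixel jitter; "shear" cracks carry a lateral step of
0.45 arc-radii between their halves. Bounding boxes are the exact crack
extent padded by 2 px. Cohort sampling derives per-image seeds from the
master seed (fully reproducible) and can draw fracture regions either
uniformly or from the clinical frequency distribution (range midpoints,
normalized: parasymphysis ≈ 0.34, body ≈ 0.24, condyle ≈ 0.20, angle ≈ 0.18,
ramus ≈ 0.026, coronoid ≈ 0.013). Default cohort sizes are 360 training /
60 test images.

What the synthetic images do **not** model: teeth, implants, the spine
shadow, soft-tissue superimposition, scanner-specific noise, or realistic
fracture morphology. Passing tests therefore demonstrate correctness of the
arithmetic, geometry, counts and the contrast-enhancing behaviour of the
operators — not clinical detection performance, which requires real
radiographs and trained detector weights.

## Numerical choices and edge cases

* Gaussian surrounds use scipy's sampled-kernel filter (radius
  `int(3σ+0.5)`); a sub-half-pixel σ returns the input unchanged.
* Flat tone-mapping inputs map to mid-gray (see above); `flat_epsilon`
  (1e-12) guards the degenerate-range test.
* IOU is clamped to ≤ 1 against float overshoot, and the match threshold
  comparison tolerates 1e-12 so exact-coincidence matching at threshold 1.0
  behaves as expected.
* Epoch arithmetic floors (`⌊max_batches·batch/images⌋`, e.g.
  ⌊12000·64/1080⌋ = 711); the exact rational is exposed alongside.
* MLAT weights must sum to 1 within 1e-6; scale/weight length mismatches
  are rejected.

## Known limitations

* The variant set composing the ×3 expansion treats gamma modulation as one
  of the three emitted variants; whether gamma-shifted copies should
  instead multiply the LAT variants is configurable via `BuildConfig`.
* `region_report` attributes false positives by predicted class; with
  class-agnostic matching the per-class FP attribution is nominal.
* The acceptance script's quantities are structural (counts, arithmetic);
  detection scores on clinical data are out of reach by construction.
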