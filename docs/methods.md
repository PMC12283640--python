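# Methods

## Problem and pipeline

Carotid plaque echogenicity carries risk information beyond the degree of
stenosis: echolucent (dark) components such as lipid cores and
juxtaluminal black areas (JBAs) are linked to stroke risk, while calcified
components appear bright.  When a CNN classifies plaques as asymptomatic
(ASY) or symptomatic (SY), a natural explainability question is *which of
these grayscale-defined compositions the model's class-activation map
(CAM) actually covers*.  The package implements that measurement chain:

    image + plaque mask + reference ROIs
      -> standardize (resolution, intensity, crop/resize to 512 x 224)
      -> six-band composition map inside the plaque
      -> Score-CAM / SmoothGrad over a pluggable classifier
      -> uniform coverage mask -> four overlap-proportion families
      -> per-class mean +/- std tables + classification metrics

All spatial measurements share the standardized 512 x 224 grid, because
the heatmap lives on the model-input grid and every overlap ratio needs
one coordinate system.  Composition contours are therefore computed after
resizing; whether contouring before or after resize is preferable is
genuinely open, and the after-resize choice is the only one that keeps the
four ratio families exactly consistent with the heatmap.

## Standardization

* **Resolution.** Bilinear resampling to 20 px/mm (masks and label rasters
  ride along with nearest-neighbor).  Output dimensions are
  `round(dim * 20 / density)`.
* **Intensity.** Two-reference-point linear scaling,
  `v -> clamp(round((v - M_b)(T_a - T_b)/(M_a - M_b) + T_b), 0, 255)` with
  blood and adventitia ROI medians `M_b`, `M_a` and targets `T_b = 0`,
  `T_a = 190` (configurable).  The targets sit at the ends of the
  clinically used ranges (blood 0–5, adventitia 185–190).  Medians use the
  lower-median convention so they are attained integer grayscale values;
  together with monotonicity of the map this lands the output ROI medians
  *exactly* on the targets, which is why the blood/adventitia contract
  holds on every sample rather than approximately.  Degenerate references
  (`M_a <= M_b`) are rejected with both medians named.
* **Crop/resize.** Plaque bounding box expanded by `margin_px = 10`
  (0.5 mm at 20 px/mm; "limited surrounding background" is not quantified
  anywhere, so this is a configurable default), clipped at the borders,
  then plainly stretched to 512 x 224 without preserving aspect ratio.
  Anisotropic stretch is a documented limitation of the uniform-size
  convention itself; provenance records both transforms.

Order of operations is resolution -> intensity -> crop/resize.

## Composition bands

Bands partition [0, 255]: black GS <= 25 (lipid core / JBA), blue
25 < GS <= 50 and green 50 < GS <= 75 (fibro-fatty), yellow
75 < GS <= 100 and orange 100 < GS <= 125 (intermediate), red GS > 125
(calcified).  No morphological cleanup is applied — the contours are raw
threshold bands.  Display colors are fixed RGB (black, blue, green,
yellow, orange, red) and the contour rendering is exactly invertible
inside the plaque.

## Classifier contract and the band oracle

Downstream attribution needs only `predict_proba` (probability vector
over (ASY, SY)), `activations` (channels from one internal layer) and
optionally `gradient`.  A frozen-backbone transfer-learning classifier
exposes exactly this surface, so any such model can be plugged in; the
`TrainConfig` dataclass documents and validates the reference training
recipe (dense 128 + dropout 0.6, batch 12, RMSprop at 1e-4 with step
decay 0.6 every 7 epochs, early-stopping patience 20, rotation/flip/shear
augmentation, seeds 7/12/42).  No trainer ships with the package — the
deterministic band oracle below fills the contract for testing and for
the synthetic studies.

The **band oracle** scores a plaque by the share `f` of its pixels in one
attended grayscale band: the class probability is the softmax of
`(a f, -a f)` with sharpness `a = 2` (kept small so channel weights stay
roughly proportional to band content rather than saturating).  Its
conventions:

* **Anechoic floor.** Pixels at or below GS 5 — the blood reference range
  after normalization — count as background, not tissue.  Without this,
  Score-CAM's multiplicatively masked inputs (background attenuated toward
  zero) would read as "black tissue" everywhere and channel weights would
  lose all discrimination.
* **Plaque-restricted activations.** Channels are blurred indicators of
  (i) the attended band and (ii) bright pixels (GS > 125), both inside the
  plaque mask, plus one constant channel; they are smoothed (sigma = 2 px,
  kept below the channel-grid stride of 8) and block-averaged onto a
  28 x 64 grid.  Restricting to the plaque mirrors the fact that the score
  itself is a plaque statistic.
* **Gradient.** The hard band indicator has zero derivative almost
  everywhere, so the analytic gradient differentiates a smooth Gaussian
  band-membership surrogate centered on the band.  This is a documented
  surrogate, used by SmoothGrad only.

An intensity-band detector under multiplicative masking has irreducible
crosstalk: tissue dimmed by a channel's upsampling ramp sweeps through the
dark band on its way to zero.  The anechoic floor removes most of it; a
small residue remains on phantoms with very large calcified areas, which
is why the Score-CAM localization property is stated over a fixed suite
rather than claimed universally.

## Score-CAM and SmoothGrad

Faster Score-CAM: take the model's activation stack; keep the `k = 3`
channels with the largest spatial variance (stable sort; the selection
statistic for the "few channels" speedup is not standardized, so variance
is the documented, configurable choice); bilinear-upsample each to the
input grid and min–max normalize (constant channels become all-zero
masks rather than being dropped); perturb the input by element-wise
product; weight each channel by the target-class probability of the
perturbed input minus that of an all-zero baseline (the original
Score-CAM increment convention, with softmax probability as the score);
output ReLU of the weighted sum, min–max normalized to [0, 1].  If the
pre-normalization field is identically zero the heatmap is flagged
*degenerate* — the modeled "no visualization possible" failure mode —
and excluded (but counted) downstream.  `k = None` gives exhaustive
Score-CAM, which equals the faster variant whenever `k` covers the stack.

SmoothGrad averages `|gradient|` over `n = 20` Gaussian-noise perturbations
with sigma = 0.30 of the image's dynamic range (both configurable,
seeded, bit-reproducible).  Models without gradients raise rather than
silently falling back to finite differences on a 114k-pixel grid.

Overlays use the continuous jet colormap alpha-blended over the grayscale
image, optionally restricted to the plaque; degenerate maps raise an
explicit error instead of rendering an image of zeros.

## Overlap quantification

Coverage is the set of plaque pixels with heatmap value strictly above
`tau = 0`: the parameter-free reading of "use all heatmap values" that
still excludes exact zeros.  A CAM-value threshold is deliberately not
introduced (any particular cut would bias which compositions count as
covered); `tau` exists only for sensitivity analyses.  Per plaque:

* `GTplq-Heatmap = 100 |coverage| / |plaque|`
* `CtoGT = 100 |C| / |plaque|` per band C
* `HMPinC = 100 |coverage ∩ C| / |C|` (0 with a presence flag when the
  band is absent)
* `HMPC = 100 |coverage ∩ C| / |coverage|` (sums to 100 across bands)

The chain identity `HMPC * GTplq-Heatmap = HMPinC * CtoGT` (as fractions)
holds exactly and is asserted per sample in the tests.  Class summaries
are mean +/- sample (n-1) std over non-degenerate samples; degenerate
samples are counted separately; with one sample the std is reported as 0
with a flag, and an all-degenerate class is reported empty, never zero.
Both aggregation modes for absent compositions (zero-included or
excluded) are available.

## Classification metrics

SY is the positive class (sensitivity reported with the symptomatic
class, the clinical convention).  Accuracy, sensitivity, specificity and
per-class precision/F1 follow the standard confusion-matrix formulas;
zero denominators are reported as undefined with a named reason, never as
0.  AUC is the Mann–Whitney rank statistic over per-sample SY
probabilities (ties half credit), computed via scikit-learn and
cross-checked against exhaustive concordant-pair counting in the tests.
Prediction ties at probability 0.5 break toward ASY (fixed for
reproducibility).

The stratified split applies per class: `test = floor(0.2 n)`, then
`val = floor(11/95 * remaining)`, rest train — the only scheme consistent
with partitioning a balanced 236-image cohort into 168/22/46 with
84/11/23 per class.  Splitting is by sample id; patients contributing two
images are not modeled.

## Synthetic phantoms

The generator emulates the statistical structure the analysis assumes,
not ultrasound physics.  Layout per image: a near-anechoic lumen band
(base GS 2) on top, a bright adventitia band (base GS 208) at the bottom,
a tissue background (base GS 58), and an elliptical plaque between them.

* **Compositions.** Per class, composition fractions are a Dirichlet draw
  around class means — ASY (0.30, 0.18, 0.14, 0.11, 0.09, 0.18), SY
  (0.50, 0.20, 0.12, 0.08, 0.05, 0.05) over (BK, BL, G, Y, O, R),
  concentration 60.  The means encode the qualitative cohort pattern
  (dark areas largest in both classes, larger in SY; ASY mixing echogenic
  and echolucent tissue); they are explicitly not measured values, and
  are configurable.
* **Blobs.** The plaque interior is tiled by one convex blob per
  composition via additively-weighted (power-diagram) nearest-seed
  assignment with quota-matched weights (best iterate kept; seeds at
  least 0.4 semi-minor-axes apart, since near-coincident seeds make the
  quota iteration oscillate).  With `jba_adjacent_to_lumen` the black
  blob is anchored at the plaque's lumen-side boundary (JBA geometry);
  the flag is drawn with probability 0.3 (ASY) / 0.7 (SY).
* **Geometry.** Plaque axes are sampled in mm (major 13.85 +/- 4.85 mm,
  minor 4.8 +/- 1.6 mm, truncated) and converted at the per-image pixel
  density, drawn from N(14.3, 3.0) px/mm truncated to [8, 22] — the
  spread of mixed-machine acquisitions.  The canvas adapts to the plaque
  so resolution normalization is non-trivial per image.
* **Noise and jitter.** Blob interiors are drawn at band-center
  intensities (12, 38, 63, 88, 113, 180), multiplied by unit-mean gamma
  speckle (strength 0.35), blurred with a 1 px Gaussian, then scaled by
  gain U(0.75, 1.25) and shifted by offset U(0, 25).  Offsets shift the
  black level upward only: a downward shift combined with display
  clipping at 0 censors the blood reference, and no two-point linear
  method can invert a censored map — such images violate the
  normalization method's own preconditions rather than testing it.
  Band centers keep post-speckle pixels mostly inside their band, so
  composition recovery after standardization is good but deliberately
  imperfect (the tests require only >= 70% pixel agreement with the
  generator truth).

What the phantoms do **not** emulate: beamforming, attenuation, acoustic
shadowing, anisotropic speckle, real plaque morphology, inter-observer
mask variability, or any video dynamics.  Passing the synthetic suites
therefore shows that the measurement chain is correct under a known
generative truth — not that any classifier's clinical behavior is
reproduced.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy `default_rng`);
dataset generation is byte-reproducible.  The test and acceptance suites
use 200-phantom standardization and end-to-end studies, a 50-phantom
Score-CAM localization suite, and 1,000 random 16 x 16 rasters for the
overlap identities — sizes chosen so the whole suite runs in well under a
minute of compute per study while keeping Monte-Carlo errors an order of
magnitude below the tested margins.

## Known limitations

* The uniform-size resize distorts aspect ratio; small plaques are
  stretched most.
* The band oracle is an intensity detector: multiplicative masking
  induces dark-band crosstalk (see above), and its gradient is a smooth
  surrogate, not the derivative of the hard score.
* `HMPin` for absent compositions is a convention (0 with a flag), and
  class averages depend mildly on which aggregation mode is chosen.
* The coverage rule (strictly positive CAM support) is one reading of
  "use all heatmap values"; `tau` sensitivity is reported, not resolved.
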