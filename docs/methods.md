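# Methods

## Problem and design

`wsus` implements a controlled comparison between weakly-supervised and
fully-supervised deep-learning diagnosis of breast-ultrasound-like images.
The weakly-supervised arm trains a convolutional classifier from image-level
labels only (benign vs malignant) and localizes the lesion post hoc from its
class activation maps (CAM). The fully-supervised arms classify a square
region-of-interest (ROI) crop around a lesion annotation — either the
ground-truth mask ("manual") or a mask predicted by a trained segmenter
("automated"). Because no public dataset with this exact structure exists,
the package ships a synthetic B-mode phantom generator whose defaults mirror
the study design the pipeline is built for: 500+500 training images (with a
100+100 tuning subset), 100+100 internal-validation and 100+100
external-validation images, the external split rendered under a different
machine profile to emulate a vendor domain shift.

## Phantom generator

Each phantom is a grayscale image in [0, 1] with exactly one lesion and its
binary ground-truth mask.

**Background.** A smooth horizontal tissue banding (sum of three
random-phase low-frequency cosines, amplitude `layer_contrast`) multiplies a
unit-mean Rayleigh speckle field whose fluctuation amplitude is
`speckle_scale` (parameterized as contrast because a raw Rayleigh scale
would be removed by the later normalisation). The product is blurred by a
Gaussian point spread (`blur_sigma`), divided by its 99th percentile,
multiplied by `gain`, clipped to [0, 1] and raised to `gamma`. This is a
first-order B-mode approximation: no RF signal, beamforming, or
depth-dependent attenuation is modelled.

**Lesions.** Benign lesions are ellipses — wider than tall (axis ratio
0.45–0.8, near-horizontal orientation), moderately hypoechoic
(echogenicity offset −0.45 to −0.2), sharp-margined, with optional
posterior enhancement. Malignant lesions are star-shaped: the ellipse polar
radius is modulated by 4–12 sinusoidal spicules of relative amplitude
0.2–0.45, taller axis ratios and free orientation, deeper hypoechogenicity
(−0.6 to −0.3), blurrier margins, and optional posterior shadowing. Masks
are rasterised analytically and reduced to the single 4-connected component
containing the centre. Lesion diameters are drawn from 10–50 % of the image
width, dominated by small lesions relative to the field of view. The
composite adds the echogenicity offset through a Gaussian edge ramp of
width `margin_sharpness`, a seeded internal echotexture proportional to the
lesion contrast, and a soft-edged posterior column (lesion width, from the
bottom tangent to the image bottom) shaded by `posterior_effect` × 0.5.

**Domain shift.** The external profile uses speckle contrast ×1.3, blur
+0.5 px and gamma 1.2 relative to the internal profile — enough to be
detectable (per-image background-texture variance separates the splits at
p ≪ 0.01 over 100 vs 100 images) and to degrade, but not destroy,
classifier transfer.

**What the phantoms do not emulate.** Tissue-composition strata
(fat/fibroglandular/heterogeneous), calcifications, multiple lesions,
anatomical context (ribs, pleura), probe-pressure and depth-gain artifacts.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that the study design behaves as expected on images with the
right first-order statistics — not clinical performance.

## Classifier

The default backbone ("tiny") is four 3×3 stride-2 convolution + ReLU
blocks (8→16→32→K channels, K = 32 by default) — sized for single-CPU
training at 128×128. A "small" six-block variant is available. The final
feature maps `f_k` are collapsed by global average pooling implemented as
the spatial **sum** `F_k = Σ_{i,j} f_k(i,j)` (a mean-pooling switch exists;
the two differ only by a constant absorbable into the head weights, so the
summed form is the default). A bias-free linear head gives class scores
`S_c = Σ_k w_{k,c} F_k`; softmax yields class probabilities and the
probability of malignancy (POM) is the malignant-class probability. The
bias-free head makes CAM an exact decomposition of the class score:
`Σ_{i,j} M_c(i,j) = S_c`.

Setting K equal to the number of classes recovers the literal
one-feature-map-per-class configuration; the default K = 32 is the standard
CAM formulation. All layers are He-initialised (fan-in, gain √2) from a
seeded generator.

**Training.** Cross-entropy plus an L2 penalty (λ/2·‖W‖², applied to weight
matrices, not biases), Adam with learning rate 10⁻³, β₁ = 0.9, β₂ = 0.999,
batch size 64. Epoch count is a free design choice (the recipe above fixes
everything else); the study default is 50 epochs with best-tuning-AUC
snapshot selection, which on default phantoms brings the weak arm to
internal-validation AUC ≈ 0.9 or better. Without a tuning set the
final-epoch parameters are kept and a warning is logged. A grid-search
utility evaluates a learning-rate × weight-decay grid on a stratified
tuning subset (ties broken toward lower weight decay, then lower learning
rate) and retrains the winner on the whole training set.

The network stack itself (convolution, pooling, upsampling, Adam,
handwritten backpropagation) is a compact numpy implementation in
`wsus.nn`; every layer's gradient is verified against numeric
differentiation in the test suite, and training is bit-reproducible per
seed.

## CAM localization

`M_c = Σ_k w_{k,c} f_k` at feature resolution, min–max scaled (a constant
map is flagged degenerate and scored as a failed localization rather than
an error), bilinearly upsampled to the annotation resolution, and
binarized at the inclusive threshold 0.3. Localization is correct when the
binary map overlaps the ground-truth mask by at least one pixel. The class
whose CAM is evaluated is configurable — predicted class (default), true
class, or always-malignant — because "discriminative localization"
conventionally refers to the class the model actually predicts. An optional
utility re-tunes the threshold by maximising mean Dice overlap on a
calibration set; the default pipeline keeps 0.3 fixed.

## Segmenter

A compact U-Net (three 2×2 max-pool stages, nearest-neighbour upsampling,
skip concatenations, 8-channel base width, sigmoid output) trained with
binary cross-entropy plus soft-Dice (smoothing 1, per-image), Adam with the
same optimizer constants. The study default trains on 150+150 training
images for 10 epochs — enough for held-out Dice ≈ 0.8–0.85 on default
phantoms at a few minutes of CPU time. Predicted masks drive the
automated-ROI arm; an empty predicted mask falls back to the whole image
(counted and reported). Training rejects empty target masks up front.

## Preprocessing

Whole images and ROI crops are bilinearly resized to the classifier side
(128 default, 224 supported) and normalised by their post-resize maximum,
so the maximum is exactly 1. ROI crops take the mask bounding box, expand
it by a fixed 30-pixel margin on all sides, then square the shorter
dimension symmetrically (margin first, so the stated margin is exact along
the longer side), clip to image bounds (accepting a non-square crop at
borders rather than padding), and resize. Coordinates are 0-based and
half-open; masks use nearest-neighbour interpolation.

## Statistics

* **AUC** — Mann–Whitney with half-credit for ties; variance by DeLong's
  structural components; 95 % CI is Wald on that variance, clipped to
  [0, 1].
* **DeLong test** — covariance of two AUCs from shared placement values;
  two-sided normal p. Identical score vectors (zero-variance difference)
  return p = 1 by convention. The test suite checks the
  variance/covariance against a leave-one-out jackknife and the null
  rejection rate by simulation.
* **Exact McNemar** — binomial(b + c, ½) doubling of the smaller tail,
  capped at 1; b = c or no discordant pairs give p = 1. Used for paired
  sensitivity (malignant cases only) and specificity (benign cases only)
  at the operating point.
* **Fisher's exact test** (two-sided, point-probability method) — compares
  benign vs malignant localization rates; cross-checked in tests against a
  direct hypergeometric summation.
* **Dice** — exact pixel-count formula 2|A∩B|/(|A|+|B|); undefined (error)
  only when both masks are empty.
* **Operating point** — POM ≥ 0.5, configurable; the only threshold-free
  default for a softmax binary head.
* Significance is read at two-tailed 0.05; no multiple-testing correction
  is applied.

## Study orchestration

One weak classifier (whole images), one ROI classifier (ground-truth-mask
crops), one segmenter. The two fully-supervised arms share the ROI
classifier and differ only in the evaluation-time crop mask — this makes
"perfect segmenter ⇒ identical POMs" an exact identity rather than an
approximation. Arms are evaluated on identical, identically-ordered case
rosters; train/validation roster disjointness is asserted at run start.
Sub-seeds for generation and each training stage are derived from the
master seed via a seed sequence, so the whole study is a pure function of
(config, seed); the results JSON rounds floats to 6 places to make
reproducibility byte-comparable.

Default problem sizes (128×128 images, tiny backbone, 50-epoch classifiers,
300-image/10-epoch segmenter) were chosen so a complete study runs in
roughly ten minutes on one CPU core.

## Known limitations

* Phantom realism is first-order only (see above); absolute AUCs on
  phantoms are not comparable to clinical values.
* The Wald AUC CI can be anti-conservative near AUC = 1 with small n.
* The numpy network stack supports the architectures it ships
  ("tiny"/"small" classifiers, the compact U-Net); published large
  backbones are out of scope.
* Mean-pooling GAP, alternative CAM class policies and threshold re-tuning
  are provided but deliberately not exercised by the default study.
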