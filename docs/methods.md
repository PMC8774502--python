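# Methods

## Problem setting

Dermoscopy archives used to train benign/malignant lesion classifiers can
contain segmentable acquisition artefacts that co-occur with one class. The
motivating case is elliptical colour-calibration patches that appear near
the image border in roughly half of the benign images and in none of the
malignant ones, making patch presence a perfect predictor of the benign
label. A classifier that exploits this shortcut looks accurate on held-out
data drawn from the same archive while having learned, in part, a rule
("coloured patch ⇒ benign") that cannot transfer.

`patchaudit` quantifies this reliance with counterfactual images and
corrects it by de-biasing the training set:

1. **Removal audit.** For benign test images with patches (set *A*),
   segment the patch, dilate the mask, inpaint it away, and compare the
   predictions for the original and the inpainted image.
2. **Insertion audit.** For malignant test images without patches (set
   *B*), composite a real patch template (extracted from the training
   set) into the image at a lesion-disjoint boundary location and compare
   predictions.
3. **Validity check.** Before trusting either audit, verify on patch-free
   images that inpainting *random* elliptical regions barely moves the
   classifier (mean ΔP ≈ 0) and keeps images in-distribution (high SSIM).
4. **Footprint control.** For the insertion audit, additionally inpaint
   the exact footprint the patch would have covered, without compositing
   it. If prediction shifts come from the patch content rather than from
   occluding that area, the control ΔP distribution concentrates much
   closer to zero than the insertion ΔP distribution.
5. **Correction.** Replace every detected patch in the *training* set by
   its inpainted version, retrain the same architecture, and repeat all
   audits for the retrained classifier.

## Deviation statistics

With classifier output P(malignant|x) + P(benign|x) = 1, all statistics
use the probability of each image's true class, so a negative deviation
always means the alteration pushed the prediction away from the truth.
For a paired set {(x_i, x'_i)} with deviations
d_i = P_true(x'_i) − P_true(x_i):

- **MAD** = mean |d_i| — magnitude of reliance.
- **%P↓** = fraction with d_i < 0 — direction of the effect.
- **MND** = mean |d_i| over the subset with d_i < 0; undefined (reported
  as null, never 0) when that subset is empty.
- **%flip** = among pairs whose original prediction was *correct* at the
  decision threshold, the fraction whose altered prediction is incorrect.
  The unrestricted variant (denominator = all pairs) is computed and
  logged alongside; the restricted one is the default because it isolates
  alteration-caused errors from pre-existing ones.
- **Sensitivity / specificity** at threshold P(malignant|x) ≥ 0.4
  (malignant positive; the boundary tie classifies as malignant). The low
  threshold deliberately favours sensitivity, as one would in a cancer
  screening setting. A metric whose class is absent from a subset is
  reported as not-applicable rather than 0.
- **Fidelity** between two classifiers = Pearson r of P(malignant|x) over
  matched images, overall and per subgroup (malignant, benign without
  patch, benign with patch). A model that only changed its artefact
  handling shows high r everywhere except the benign-with-patch subgroup.

## Synthetic data generator

Every stage is validated on generated images with ground-truth masks, so
no external data is needed. Each image (default 128×128 RGB in [0,1]) is:

- **Skin background**: per-image base tone near (0.80, 0.62, 0.55) with
  ±0.04 jitter, multiplied by a low-frequency Gaussian-filtered texture
  field (σ = side/16, ±6%), plus additive Gaussian pixel noise
  (sd 0.02).
- **Lesion**: a roughly elliptical central blob whose radius is modulated
  by a low-order Fourier series. Border irregularity (modulation
  amplitude 0.05 benign vs 0.18 malignant) and darkness (per-image
  normal around 0.28 benign vs 0.58 malignant, sd 0.10) carry the
  legitimate class signal. The contrast defaults are calibrated so that
  a classifier trained on patch-free data separates the classes with
  sensitivity and specificity ≥ 0.8 at the 0.4 threshold — the shortcut
  must be *optional*, not the only usable signal.
- **Patch** (with probability 0.46 for benign, 0 for malignant): a
  saturated ellipse with hue drawn far from skin tones (azure, blue,
  green, magenta), semi-axes 10–25% of the side, centre in the outer 25%
  border ring, hard-edged, placed disjoint from the lesion (bounded
  retry; failures emit the image patch-free and flagged).

Per-image RNGs are spawned from one master `SeedSequence`, so datasets are
bit-exactly reproducible and insensitive to generation order.

What the generator does **not** emulate: hair, rulers, gel bubbles,
vignettes, camera vignetting or colour-profile variation, lesion texture
(networks, globules), and the heavy class imbalance of real archives.
Passing audits on this data therefore demonstrates the *mechanics* of the
pipeline — segmentation, counterfactual construction, statistics,
de-biasing — not performance on real dermoscopy images.

## Segmentation

Patches are detected by SLIC superpixels (default 200 segments,
compactness 10) followed by thresholding each superpixel's mean-colour
distance to an estimated skin tone. The skin tone is the per-channel
*median* RGB (robust to the lesion and the patch); the distance is
Euclidean over `[r, g, b, w·s·cos 2πh, w·s·sin 2πh, s, v]`, which treats
hue circularly, suppresses the meaningless hue of near-grey pixels by the
saturation factor, and up-weights hue (w = 2) because calibration patches
differ from skin chiefly in hue while pigmented lesions differ chiefly in
value — the weighting separates the two kinds of off-skin region.
The threshold (1.4), superpixel count and minimum region area (25 px)
were chosen on generator images by inspecting the distance distributions
of lesion-core versus patch-core superpixels; they are configuration, not
claims about any external dataset.

A pixel-level refinement pass attaches connected components of per-pixel
off-skin colour that touch the superpixel-level mask: superpixels
straddling a patch edge dilute their mean below threshold, which can
strand saturated pixels — in the worst case at the image border, where a
later dilation cannot reach them and an inpainting fill would be tinted
by them.

Masks are dilated once with an elliptical structuring element before
inpainting so the fill cannot "repair" the patch from leftover edge
pixels. The conventional element for 224×224 dermoscopy images is 9×9;
the default here is the scale-equivalent 5×5 at the package's 128×128
working resolution (9/224 ≈ 5/128). Externally supplied masks are dilated
and used verbatim through the same path.

## Inpainting

The reference backend fills masked regions by solving the biharmonic
equation with the surrounding pixels as boundary data (classical smooth
interpolation). The audit methodology does not require a learned
inpainter — it requires an *uninformative* fill, and that property is
verified empirically by the validity check rather than assumed. Any
backend implementing `fill(image, mask)` with the contract "complement of
the mask bit-exactly unchanged, filled values in [0,1]" can be registered
(e.g. a neural inpainter wrapped in a subprocess); a conformance test
runs against every registered backend. Random validity-check masks mirror
the generator's patch geometry (semi-axes 10–25% of the side, centre in
the outer 25% ring, uniform rotation).

SSIM uses the standard Gaussian-weighted 11×11 window, σ = 1.5,
K1 = 0.01, K2 = 0.03, population window statistics, channel-averaged.
The ΔP outlier threshold is |ΔP| > 0.2; outliers are listed for
inspection, never dropped.

## Reference classifier

Logistic regression (L2, C = 1, deterministic LBFGS) over engineered
image features:

- global hue×saturation histogram (8×4 bins, scaled by `hist_weight` = 6)
  — pools colour evidence over the whole image the way a CNN pools
  feature maps, and is where the patch shortcut is learnable;
- global per-channel mean/sd and brightness percentiles (5–75);
- central-disc (radius 0.35·side) channel means and dark-end brightness
  percentiles — lesion darkness, the main legitimate signal;
- central-disc edge statistics (Sobel mean, 95th percentile, brightness
  sd) — border irregularity, in the spirit of the ABCD rule's B
  criterion.

The feature split matters for interpretation: the legitimate signal lives
in central/darkness/edge coordinates, the artefact in the global colour
histogram, so the de-biased retrained model (whose training set has no
patch mass in the saturated bins) is nearly patch-blind, while remaining
the same architecture trained the same way. The histogram scale was set
on generator data so that, with the perfect patch–benign correlation, the
regularised fit picks the shortcut up strongly — i.e. the synthetic
conditions reproduce the phenomenon under audit. Probabilities are scored
row-wise so batch and single-image evaluation are bit-identical; the
decision threshold is stored in config but applied only at metric time.

The classifier surface (`predict_proba` → records with
p_malignant + p_benign = 1; `fit`; `save`/`load`) is the full contract the
audit needs, so external models plug in via an adapter (predictions read
from CSV) without the pipeline knowing anything about them. Features are
computed from image statistics, not a fixed pixel grid, so the model is
resolution-independent; 224×224 inputs work unchanged.

## Orchestration and reproducibility

`run_debias_experiment` derives independent named RNG streams from one
master seed (`SeedSequence.spawn`), computes each counterfactual set
*once* and evaluates both classifiers against identical altered images,
and records every excluded image (no lesion-disjoint placement within 50
attempts) in an exclusion log — conservation of samples is asserted in
tests: every audited image appears in exactly one of report or exclusion
log. Identical config + seed reproduce report JSONs byte-identically.

## Problem sizes and numerical choices

The reference experiment uses 1,600 training / 400 test images at
128×128 (patches in 46% of benign training and test images), 200 images
for the segmentation-recovery measurement, and one random mask per image
in the validity check. These sizes give stable statistics (set A ≈ 90,
set B ≈ 190 test images) while keeping a full run in a few CPU-minutes.
Degenerate inputs are errors, not silent defaults: empty prediction sets,
all-pixels exclusion masks, single-class training sets, unknown backends,
and undefined MND/flip denominators all raise or flag explicitly.

## Known limitations

- The generator's artefacts are uniform hard-edged ellipses; real
  calibration charts have internal structure (colour swatches), and real
  archives carry additional correlated artefacts (rulers, hair) that the
  audit would attribute to whatever masks it is given.
- The biharmonic fill is smooth: its SSIM to textured skin is high but
  its texture is not realistic, so a texture-sensitive classifier could
  react to inpainting itself; the validity check is the guard, and a
  learned backend can be registered where it fails.
- The reference classifier is linear over engineered features; it stands
  in for the audited model class, not for a deep network's behaviour.
- Exactly one unscaled template is inserted per image; template scaling
  or per-image multiplicity is not modelled.
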