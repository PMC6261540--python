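# Methods

## Problem and model

Standard automated perimetry measures differential light sensitivity at a
fixed set of retinal locations (a *test pattern*). Clinically, fields are
summarized by global indices — the mean defect MD = −(1/L)·Σ r_l and
sLV = sqrt(Σ (r_l − r̄)² / (L−1)), the sample standard deviation of the
sensitivity deviations r_l (measured − age-normal, dB; loss negative) — but
those discard *where* the loss sits, which is exactly what distinguishes
early glaucomatous defects (arcuate bundles, nasal steps, paracentral
scotomas) from test-retest noise.

This package makes perimetric data image-like so a convolutional classifier
can exploit that spatial structure:

1. **Voronoi rasterization.** A 61×61 grid covers [−30, 30]² degrees at
   1°/pixel, with the fixation origin at pixel (31, 31). Each pixel takes the
   deviation of its nearest test location in Euclidean degree space:
   V(i,j) = r_{l*}, l* = argmin_l ‖(x_l, y_l) − (x, y)‖₂. The raster is
   piece-wise constant over the voronoi regions and identical in format for
   any test pattern (24-2, G1, …), so models are pattern-agnostic. No
   pre-smoothing is applied: smoothing is what the convolution layers learn.
   Left-eye (OS) fields are mirrored about the vertical axis to right-eye
   orientation before rasterization, which is equivalent to mirroring image
   columns but keeps the raster code laterality-agnostic.

2. **Classifier.** A deliberately small CNN maps the raster to an
   early-glaucoma probability:
   `[conv 4@3×3–BN–ReLU]×2 → pool/2 → [conv 4@3×3–BN–ReLU]×2 → pool/2 →
   conv 4@3×3–BN–ReLU → global average pool → FC32–ReLU–BN →
   FC32–ReLU–dropout(0.5) → FC1–sigmoid` (1985 trainable parameters;
   "same" padding, ceil-mode 2×2 pooling: 61→31→16). Baselines: raw MD, raw
   sLV, their fusion MD+sLV, and a flat NN with the same dense head applied
   to [deviation vector, MD, sLV] (no spatial information).

3. **Saliency.** The gradient of the output probability w.r.t. the input
   image (signed), averaged over n = 500 Gaussian perturbations with
   σ = σ_r·(VI_max − VI_min), σ_r = 0.05 (*SmoothGrad*), and optionally
   averaged within each voronoi region (*piece-wise* map, one value per
   tested location). Maps are min-max normalized to [0, 1] for display;
   a constant raw map normalizes to all zeros ("no influence anywhere").

4. **Evaluation.** Average precision of the ranking (step-wise
   AP = Σ (R_k − R_{k−1})·P_k over descending unique thresholds, ties
   grouped) under k-fold cross-validation grouped by *subject*: every
   examination of a subject, both eyes, lands in exactly one test fold.
   Neural methods are retrained several times per fold with distinct seeds;
   medians and sample standard deviations are taken over all cumulated AP
   entries. A literal product-integral variant of AP (∫ PPV·TPR dt over the
   rescaled threshold) is provided as a documented secondary metric
   (`ap_product_integral`); it is not the standard AP and is not used in
   reports. Operating thresholds, when needed, maximize
   PPV·TPR/(PPV + TPR), a monotone rescaling of F1.

## Numerical implementation of the networks

The networks are small enough that the package implements them directly in
numpy (`voroperim.nets`) rather than through a deep-learning framework:
layers with exact reverse-mode gradients (convolution as 9 shifted GEMMs,
batch norm with momentum 0.9 / eps 1e−3, ceil-mode max pooling with
first-occurrence argmax tie-breaking, inverted dropout), Glorot-uniform
initialization from a seeded generator, Adam (lr 1e−3, β₁ 0.9, β₂ 0.999) on
binary cross-entropy with batch size 32. Optimization runs in float32;
selected checkpoints are cast to float64 so inference is batch-size
independent and input gradients match central finite differences to
≤1e−4 relative error. Training keeps the checkpoint with the lowest
validation loss over a 100-epoch default budget; the validation split holds
out ~10% of training *subjects*, stratified by class. Fixed seeds make
initialization, batching, dropout and the selected checkpoint reproducible
on one device.

Degenerate inputs are handled explicitly: a pixel equidistant from several
seeds goes to the lowest seed index; blind-spot locations are excluded from
voronoi seeding and from MD/sLV by default (configurable); SmoothGrad on a
constant image (σ = 0) degenerates to the plain gradient; single-class
score vectors are rejected rather than given an arbitrary AP.

The MD+sLV fusion is not uniquely defined by the two indices alone; the
package fits a two-feature logistic regression on the training fold
(primary) and offers a label-free rank-sum fallback. Both are
interpretations; the cross-validation protocol uses the logistic variant.

## Synthetic cohorts

The generator (`voroperim.synthetic`) emulates the statistical shape of
longitudinal clinical perimetry cohorts, not their physiology:

* **Control fields** = per-eye offset ~ N(+0.31, 1.0²) dB plus independent
  per-location noise ~ N(0, 1.84²) dB. The offset mean and noise scale are
  calibrated so the control group matches reported clinical cohort
  statistics (mean MD ≈ −0.31 dB, mean sLV ≈ 1.84 dB).
* **Early-glaucoma fields** add a persistent focal defect of depth
  N(14, 4²) dB at one *archetype* — superior/inferior arcuate (the 10–20°
  annulus of one hemifield), nasal step (superior nasal wedge beyond 15°),
  superior paracentral (within 10°) — or a mild diffuse depression
  (N(2.5, 0.8²) dB everywhere). Archetypes are stored as plain location
  index lists (data, not code) and derived geometrically from the pattern
  when not supplied. Defects deepen by 0.3 dB per visit; the archetype and
  per-eye offset persist across visits (longitudinal consistency).
* Both groups are rejection-sampled to MD < 6.0 dB, the usual early-stage
  inclusion cap.

What passing tests on this generator show: the pipeline separates cohorts
whose group difference is a localized, spatially structured sensitivity
loss clearly above the noise floor, with zero subject leakage, and degrades
to the prevalence regime when that difference is removed. What they do not
show: performance on real fields, whose noise is not Gaussian or
location-independent (fatigue, fixation losses, learning effects, floor
effects), whose defect geometry is more varied, and whose class boundary
(MD close to the 6 dB cap, mixed diffuse+focal loss) is far harder. The
shipped 24-2 pattern follows the standard published grid; the shipped G1
file is a synthetic 59-location stand-in with a centrally condensed layout,
not the clinical chart (pattern-exact tests use toy patterns).

## Study sizes and defaults

The packaged end-to-end study (`voroperim.study`) uses 20 control + 20 EG
subjects, one eye, three visits (120 fields), 10-fold subject-grouped CV
with 2 training repeats and a 25-epoch budget — sizes chosen so a complete
run takes minutes on a single CPU while still exercising every component at
full fidelity. The zero-depth null study uses 5 folds, one repeat and 10
epochs, since only the regime (AP ≈ prevalence) is of interest there.
Fold assignment shuffles subjects within class before round-robin dealing,
so fold sizes differ by at most one subject and class mix stays close to
the cohort's; at clinical cohort sizes this coincides in distribution with
an unstratified shuffle, while at packaged-study sizes it avoids
single-class test folds on which AP is undefined.

Key defaults: saliency n = 500, σ_r = 0.05; CNN/NN batch size 32, Adam lr
1e−3, 100-epoch budget (25 in the packaged study), dropout 0.5, 32 hidden
units, 4 filters per conv layer; generator as above, seed-deterministic to
the byte.

## Known limitations

* The CNN is intentionally tiny; it is a spatial-feature probe, not a
  state-of-the-art classifier, and its AP variance across folds is large on
  small cohorts.
* Gaussian, location-independent noise understates the difficulty of real
  perimetry; results on synthetic cohorts are an upper bound on ranking
  quality at a given defect depth.
* Only AP is reported (no ROC/AUC, calibration, or significance testing
  between methods).
* The voronoi raster quantizes locations to 1°; two locations closer than a
  pixel would merge (no shipped pattern does this).
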