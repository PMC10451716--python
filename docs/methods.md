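# Methods

`patchtest` implements an end-to-end analysis for automated reading of
epicutaneous patch tests from multi-modal skin imagery: chamber-ROI
pre-processing, binary reaction classification, cross-modality feature
fusion, and the paired statistics used to compare classifiers.  Because the
clinical dataset this kind of analysis targets is not publicly available,
the package ships a synthetic phantom generator that reproduces the
statistical structure the pipeline relies on; every mechanism the pipeline
is designed to expose can therefore be exercised and tested end to end.

## The problem

A patch test applies allergen-filled chambers to the upper back; after
removal, each chamber's skin area is read on the ICDRG scale
(none/irritant, `+`, `++`, `+++`).  A multi-spectral camera images each
patch as two adjacent capture areas and exports six co-registered
"modalities" per capture: the plain color image, a false-color hemoglobin
map (redness), and four texture-family maps (texture, fine lines, folds,
volumes).  The analysis collapses grades to a binary reading (`none`/
irritant negative, everything else positive) and asks three questions:

1. how should a chamber's region of interest (ROI) be presented to a
   classifier (pre-processing comparison);
2. which single modality classifies best (modality comparison);
3. does fusing two modalities' learned features beat the best single
   modality (fusion investigation)?

## Pre-processing schemes

* **Crop** — the ROI sub-rectangle alone.
* **Alpha Mask (AM)** — the full image multiplied element-wise by a mask
  `M` that is 1 inside the ROI and 0.5 outside (`I' = I ⊙ M`): the ROI is
  highlighted, the context stays visible at half brightness.  The product
  is exact up to integer rounding; ROI pixels are bit-identical.
* **CEAM** — AM plus a 75-row strip from the adjacent capture area,
  concatenated along the shared physical edge (bottom of area 1 ↔ top of
  area 2); for area-2 images the ROI's vertical coordinates shift down by
  the strip height.  The strip is dimmed like any other context.  With a
  0-row strip CEAM degenerates exactly to AM.

Masking operates on raw pixel values; resizing (224×224 bilinear) and
per-channel ImageNet normalization happen afterwards in the model
transform, which at train time also applies seeded horizontal/vertical
flips (p = 0.5 each) and rotation uniform in ±20°, with black fill.

## Classifier

The classifier is a compact fully connected network over a fixed image
featurization, trained exactly like a fine-tuned CNN would be: AdamW,
batch size 8, cosine-annealed learning rate from 3·10⁻⁴ to 1·10⁻⁵
(`lr(t) = lr_end + (lr_start − lr_end)(1 + cos(πt/(T−1)))/2`), binary
cross-entropy on the positive-class sigmoid, decision threshold 0.5, all
randomness driven by one seed.  The featurization has three stages:

1. **Saliency anchoring** — the image is translated so its brightest
   region (after smoothing) is centered.  Alpha-masked samples keep the
   ROI at full brightness while dimming everything else, so this centers
   the ROI; it plays the role of the translation invariance a
   convolutional extractor provides, using image content only.
2. **Block pooling** — each channel is averaged to a `pool × pool` grid.
3. **Center-surround contrast** — each cell minus its 3×3 neighborhood
   mean, concatenated with the raw grid.  This encodes how a region
   differs from its immediate context, the cue that separates a reaction
   confined to the ROI from erythema spilling in from a neighbor.

Two backbones are registered: `pooled-mlp-1280` (14×14 grid, one
1280-unit penultimate layer — the default, with the penultimate width
typical of compact image backbones) and `pooled-mlp-tiny` (8×8 grid,
256→128 head) used by the desk-scale profile (`TrainConfig.reduced()`:
tiny backbone, no augmentation, tens of epochs, weight decay 0.05).  The
penultimate-layer activations are exposed as the learned features for the
fusion stage.  The default profile (250 epochs, augmentation on)
reproduces the full training protocol when resources allow; the tests and
the acceptance script use the reduced profile with 112-pixel transforms,
whose problem sizes (cohorts of 32–100 patients, 256–1200 chambers) keep
a full run in minutes on one CPU.

Every fit asserts train/validation patient disjointness first; all splits
(70/30 hold-out, 5-fold, 5×2) are patient-grouped, with fractional
patients rounded toward the training side.

The pre-processing comparison defaults to the color modality; the choice
is configurable because accounts of comparable study designs differ on
whether color or redness was used for this step, and the comparison's
logic is indifferent to it.

## Statistics

* **Metrics** — recall, specificity, precision, accuracy, F1 from the
  standard confusion-matrix definitions; zero-denominator ratios are
  reported as NaN with a warning, never silently 0.
* **McNemar** — on the discordant pairs (b, c) of two classifiers
  evaluated on identical chambers: exact two-sided binomial test at 0.5
  when b + c < 25, else the continuity-corrected χ²₁ statistic
  `(|b−c|−1)²/(b+c)`; b + c = 0 returns p = 1 by convention.
* **Combined 5×2 cv F-test** — ten performance differences p_ij from five
  2-fold repetitions; `F = Σ p_ij² / (2 Σ s_i²)` against F(10, 5).  The
  difference fed in is the F1 difference by default.  All-zero fold
  variances (classifiers behaving identically) yield NaN with a warning.
* **Fold aggregation** — sample (ddof = 1) mean ± sd per metric;
  confusion matrices pooled by summation.
* **Allergen error report** — per-allergen false-prediction percentages
  pooled over folds; Z-scores across allergens with the population
  (n-denominator) sd; outlier ⇔ |Z| > 3; zero variance ⇒ all Z = 0.
* **Fusion** — per-chamber Pearson correlation between two modalities'
  feature vectors, summarized as mean ± sd of |r| (zero-variance chambers
  skipped with a warning); fusion classifier is an RBF-SVM with C = 3.5,
  the "scale" gamma heuristic, and feature standardization fit on the
  training side only (RBF kernels are scale-sensitive; raw deep
  activations are not standardized).  Decision scores map to labels by
  sign; no probability calibration.

Two-sided tests at α = 0.05 throughout; no multiple-testing correction is
applied across pairwise tables.

## The phantom

`PhantomConfig` defaults mirror the emulated study: 200 patients, two
480×480 capture areas per patch, six 110 px chambers per area in a
2-column grid, grade probabilities (0.61, 0.18, 0.19, 0.02), the 72 h
timepoint only.  Rendering is deliberately non-physical: each modality is
a deterministic two-anchor colormap over a scalar field (hemoglobin,
visible erythema, roughness, depth, volume), because downstream code needs
consistent label-correlated RGB statistics, not skin optics.  Structure
the generator does emulate:

* graded erythema, strongest and most localized in the hemoglobin field
  (blob σ 0.40·chamber vs 0.55·chamber for visible erythema), with ~8%
  severity jitter so grades overlap slightly;
* per-patient baseline hemoglobin offsets (sd 0.06) — the vasomotor
  variation that makes *absolute* ROI redness unreliable and comparison
  against the surrounding skin informative;
* per-chamber visible-expression variability (visible weight ~ U(0.25, 1)
  while hemoglobin always expresses), which is why redness is the
  strongest single modality in the default mode; a `complementary` mode
  instead routes each positive chamber's signal predominantly into one of
  color/redness, the condition under which fusion helps;
* textural aberrations (all four texture-family maps) only for `++`/`+++`
  reactions;
* **bleed**: with configurable probability a strong reaction spreads into
  one uniformly chosen adjacent chamber — including across the
  area-1/area-2 boundary — depositing reaction-like erythema at the
  victim's center plus a connecting track through the inter-chamber gap
  (spreading erythema is one contiguous patch of skin).  The victim's
  label is unchanged and the manifest records `bleed_victim` for
  analysis;
* **dye allergens**: dark pigment in the color image and a large
  hemoglobin artifact in the redness map regardless of grade (the
  mechanism by which skin-staining allergens corrupt hemoglobin maps).

Everything is deterministic given the seed (per-patient child seeds), so
identical configurations are byte-identical.  PNG output is lossless;
JPEG (quality 95) mirrors the camera software's export format.

### Reference scenarios

`patchtest.scenarios` pins four desk-scale cohorts, one per mechanism
(bleed, modality ranking, complementary fusion, dye).  Their parameters
were chosen from mechanism analysis, not tuned to outcomes:

* the **bleed** scenario makes weak (`+`) reactions rare (12%) and extreme
  ones common (38%) with certain bleed, so a moderate-erythema ROI is
  usually a bleed victim and only context can say so; 32 px chambers in
  160 px images keep reaction halos and bleed tracks out of neighboring
  crop boxes (with larger chambers the halo leaks into the adjacent box
  and cropping can detect bleed without context, voiding the comparison);
* the **dye** scenario uses the study's observed grade mix with PPD as the
  staining allergen.

### What the phantom does not capture

No skin optics, 3-D surface reconstruction, chamber-imprint geometry,
hair/marker artifacts, longitudinal 0/48/72 h dynamics, or inter-patient
anatomical variation; chamber boxes are exact and noiseless, whereas
clinical boxes are hand-traced.  Passing the directional checks therefore
shows that the pipeline detects each mechanism when present with the
configured effect sizes — not that the achieved F1 levels transfer to
clinical images.

## Numerical choices and degenerate inputs

Integer images are masked with rounding to nearest; ROI pixels are exact.
Percentages round half away from zero.  The exact McNemar p-value follows
the two-sided binomial convention (summing outcome probabilities not
exceeding the observed one).  The phantom rejects configurations whose
chamber grid cannot be placed without overlap, grade probabilities that do
not sum to 1 (tolerance 1e-9), and dye allergens absent from the panel.
Empty manifests, empty training sides, single-class SVM training sides,
too-few patients for a split scheme, and sub-3-allergen Z-reports all
raise errors rather than degrade silently.

## Known limitations

The backbone is a compact network over a fixed featurization, not a deep
CNN: it reproduces the mechanisms, learning dynamics, and interfaces of
the full protocol at desk scale, but its absolute accuracy on clinical
imagery would be well below a fine-tuned modern CNN, and its saliency
anchor assumes alpha-style highlighting (for crop samples it centers on
the reaction, which is serviceable but meaningless for localization).
The 5×2 fusion stage reuses features from one 70/30 split's validation
side rather than re-extracting per repetition, so its repetitions share
the feature extractor.  Z-score outlier detection assumes enough allergens
for the across-allergen moments to be meaningful.
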