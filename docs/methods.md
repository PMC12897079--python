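# Methods

`lesionroi` implements a segmentation-guided preprocessing and evaluation
framework for a binary jaw-lesion classification problem — distinguishing
an ameloblastoma-like class (AME, label 1) from an odontogenic-
keratocyst-like class (OKC, label 0) on axial slices of volumetric
grayscale images with voxel-aligned lesion masks. Because no imaging data
are distributed with the package, a synthetic phantom cohort with the same
statistical structure stands in for real scans; every stage downstream of
the generator is the same code a real NIfTI cohort would flow through.

## The comparative question

Given a lesion mask, four model inputs can be derived from each selected
axial slice:

1. **original** — the untouched slice;
2. **bbox** — a square crop centered on the lesion bounding box, side
   enlarged by 20% (`ceil(1.2 * max(h, w))`), zero-padded at image
   borders;
3. **precise** — the bbox crop with every pixel outside the lesion mask
   set to zero;
4. **expanded** — the crop masked with a morphologically dilated mask
   (disk structuring element of radius `round(margin_mm / spacing)`;
   default margin 3 mm), retaining a peri-lesional band — the bone-lesion
   interface where septa insert and the cortical rim lives.

The package's central experiment trains the same classifier on each input
variant over identical slice selections, identical patient-level folds and
identical seeds, and asks how the variants rank. The expectation embodied
in the synthetic cohort (and observed in the clinical literature this
design models) is `expanded > bbox ≳ precise > original`: the precise mask
discards the diagnostic interface, the original slice drowns the lesion in
irrelevant anatomy.

## Synthetic cohort

Each phantom patient is a `(64, 160, 160)` float32 volume at 0.5 mm
isotropic spacing (a deliberately scaled-down field of view; clinical
volumetric dental scans are 0.2–0.3 mm but would need >400-voxel grids).
Intensities are arbitrary units in [0, 1000]: background 150, lesion lumen
60, septa 650, corticated rim 750, distractors 500, additive Gaussian
noise with SD 20.

Per patient, three Bernoulli features carry the class signal, with
default probabilities taken from the reported cohort frequencies:

| feature             | P(class 1) | P(class 0) |
|---------------------|-----------:|-----------:|
| multilocular        | 0.766      | 0.281      |
| cortical disruption | 0.281      | 0.516      |
| septa present       | 0.766      | 0.281      |

A lesion is a union of 1 (unilocular) or 2–4 (multilocular) overlapping
ellipsoids with equivalent radius drawn uniformly from 6–15 mm; overlap is
forced by construction so the mask is always a single connected component.
Septa are rendered as bright shells of the locule-overlap lenses (inside
the mask); the corticated rim is a bright band just *outside* the mask
(`1 < q ≤ 1.35` in the normalized ellipsoid coordinate), with a random
69–137° sector removed and the rest attenuated when cortical integrity is
"disrupted". Two to four distractor ellipsoids (spine/airway analogues)
are placed at least two lesion-radii from the lesion centroid in every
volume, with label-independent distributions — so all class information
lives in the lesion and its margin, never in the background. This is what
makes the ROI-variant ordering testable: the `precise` variant strips the
rim signal, the `original` variant dilutes everything.

What the phantom does **not** model: photorealistic bone texture, teeth
and roots, beam hardening or metal artifacts, scanner heterogeneity,
partial-volume effects, or anatomically realistic lesion shapes. A passing
ordering test therefore shows that the pipeline recovers a
margin-localized signal through the intended geometry — not that any
particular clinical accuracy would be achieved on real scans.

## Slice selection and sampling

Per patient, the per-slice lesion area is computed along axis 0; slices
with area strictly greater than 50% of the patient's maximum survive, and
every 5th retained slice (anchored at the first) is kept. The
maximum-area slice always survives. The threshold is strict (`>`), and the
stride is applied after filtering; both are configurable.

Training draws use **MAPS** (mode-adaptive patient-centric sampling).
With `N_p` images for patient *p*, `N̄ = N_total / P`, `r_p = N_p / N̄`
and `W_p = min(r_p, 2.0)`, a training draw picks a patient with
probability ∝ `W_p`, then one of its images uniformly (an equivalent flat
per-image mode weighting each image `W_p / N_p` is available). The cap
stops image-rich patients from dominating. One epoch is `N_total` draws
with replacement. Evaluation instead visits every patient exactly once
per pass in random order, emitting all of a patient's slices contiguously,
so each case contributes equally to the metrics.

## Classifier backend

The default backend is a compact CNN implemented in numpy with explicit
forward and backward passes: three blocks of (3×3 same-pad convolution →
per-channel batch normalization → ReLU → 2×2 max pooling) with 8/16/32
channels, global average pooling, and a 32-unit dense head with a
decreasing dropout ladder, trained with AdamW (decoupled weight decay
1e-4) on softmax cross-entropy. Writing the backward pass in-package is
also what exposes the feature-map gradients Grad-CAM needs without any
deep-learning framework. Any object honouring the same contract (`fit`,
`predict_proba`, a designated convolutional feature layer) can be
substituted; the estimator follows scikit-learn conventions
(`get_params`/`set_params`, trailing-underscore fitted attributes).

Two design choices deviate from what one would use with a large
pretrained backbone, deliberately:

* **Dropout ladder 0.15/0.10/0.05** (not 0.6→0.3). Stacked heavy dropout
  is calibrated to wide (≥2048-unit) heads; on a 32-unit representation
  three dropouts at 0.6/0.45/0.3 sever the signal path — the network
  provably fails to learn even a noise-free separable toy task. The
  decreasing three-layer shape is kept; the magnitude is scaled to head
  width, and both remain configurable.
* **Two-phase learning-rate schedule.** Linear warm-up to a peak, cosine
  decay to `eta_min`, a single upward reset to `phase2_lr` at
  `phase2_start_epoch` (default 51), cosine decay to `max_epochs`
  (default 100). The defaults mirror a full-scale training run; the
  desk-scale experiments in the tests and the acceptance script pass an
  explicitly scaled schedule (28 epochs, peak 3e-3, reset at 20) because
  their epochs contain only a few optimizer steps.

Training augmentation: random horizontal flip (p = 0.5), rotation ±15°,
translation ±5%, scaling 95–105%, then normalization — a fixed linear map
of the [0, 1000] intensity scale onto [0, 1], with already-conforming
inputs passed through unchanged. Evaluation applies resizing and
normalization only (idempotent on a conforming input). The fixed scale is
deliberate: per-image min–max would re-stretch each crop's contrast,
handing the masked variants an artificial contrast boost and distorting
exactly the inter-variant comparison the pipeline is built to make. Early stopping monitors validation accuracy with
patience 10 by default and restores the best state; an overfitting monitor
reports the train–validation accuracy gap against a 0.1 threshold.

## Evaluation

Patients are partitioned into k folds (default 5), stratified by label,
with per-stratum fold sizes differing by at most one; a patient can never
appear on both sides of a split — violating this raises a hard
`LeakageError`. Metrics are computed at the slice level and, after
soft-voting (patient probability = arithmetic mean of its slice
probabilities, class 1 iff mean ≥ 0.5), at the patient level: accuracy,
precision, recall, specificity = TN/(TN+FP), and F1. Undefined ratios are
reported as NaN with a warning, never silently as 0. Fold aggregates are
mean ± sample SD (ddof = 1).

AUC is the Mann–Whitney pair statistic (ties count ½) computed by
midranks; its variance, and the covariance of two AUCs measured on the
same cases, come from DeLong's structural-components method, giving a
two-sided normal z-test for paired ROC curves. The implementation is
cross-checked in the test suite against brute-force pair counting (exact
agreement, n ≤ 12) and a within-case permutation oracle (10⁵ draws;
observed |Δp| ≤ 0.02 at n = 40, asserted at 0.05). Degenerate cases (zero
variance with unequal AUCs) are reported as NaN with a warning. Cohort
characteristic tables are tested with Pearson's chi-square *without*
continuity correction — the variant that reproduces the reported
two- and three-category p-values at three decimals — and age-like
continuous variables with a two-sided Mann–Whitney U (exact for small
untied samples).

## Interpretability

Grad-CAM weights each channel of the last convolutional activation by the
spatial mean of the target-class logit gradient, rectifies the weighted
sum, min–max normalizes (an identically zero map stays zero) and
upsamples bilinearly to the input size; the map is invariant to positive
rescaling of the gradient. Confidence curves are the ordered slice
probabilities per patient; the population SD (the slice set is the whole
population for that patient) plus the distance of the mean from the 0.5
decision line drive a two-way flag: low-confidence iff SD > 0.15 or
|mean − 0.5| ≤ 0.1. Both cutoffs are declared defaults, not empirically
derived.

## Problem sizes and numerical choices

* Desk-scale comparative runs (tests, acceptance script): 40 patients,
  3 folds, 64×64 inputs, 28-epoch scaled schedule; ~3–8 selected slices
  per patient (stride 5 at 0.5 mm axial spacing). The ordering check asks
  for the qualitative ranking (expanded > original, expanded ≥ precise)
  in at least 2 of 3 seeded replicates; with a compact CNN on a
  40-patient stochastic cohort, individual-seed inversions are expected.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; cohort, partition and training seeds are
  split so stages can be re-run independently, and a report's provenance
  block (config + seeds + version) regenerates it exactly.
* Ties: soft-vote mean exactly 0.5 → class 1 (configurable threshold);
  max-pooling gradient goes to the first maximum; the slice-area filter
  is strictly `>`.
* Network arithmetic is float32; batch-norm uses batch statistics in
  training and running statistics (momentum 0.9) at evaluation.

## Known limitations

* The phantom's class signal is cleaner than clinical data; absolute
  AUCs on it say nothing about clinical performance.
* The compact CNN is a capacity floor, not a competitive architecture;
  wide pretrained backbones would need the original dropout/learning-rate
  regimes.
* Axial-only analysis; no multi-planar fusion, no automated segmentation.
* DeLong's test at 40 patients has limited power; the pairwise p-value
  matrices are reported for structure, not for headline significance.
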