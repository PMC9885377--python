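# Methods

`mlpitfalls` reproduces, on synthetic data and at desk scale, three families
of methodological errors that inflate the apparent performance of machine
learning models in medical image analysis: violations of the independence
assumption between training and evaluation data (data leakage), misleading
performance indicators and missing baselines, and batch effects.  This note
describes the generative models, the experimental procedure, the numerical
choices, and what the synthetic setting can and cannot show about real data.

## The paired-experiment design

Every leakage experiment contrasts two model-building pipelines that differ
in exactly one methodological choice:

| experiment        | pitfall arm                          | correct arm                            |
|-------------------|--------------------------------------|----------------------------------------|
| oversampling      | balance classes, then split          | split, then balance the training set   |
| augmentation      | add jittered copies, then split      | split, then augment the training set   |
| patient split     | row-level random split of patches    | patient-coherent (grouped) split       |
| feature selection | rank features on all data, then split| split, then rank on the training set   |

Within a repetition both arms consume the *same* generated dataset, the same
split seed and the same classifier seed; only the transform ordering or the
split kind differs.  With 100 repetitions per experiment, the two per-
repetition test-set F1 vectors are compared with a two-sided Wilcoxon
rank-sum test (significance threshold 0.05, configurable).

Crucially, every default generator configuration carries **zero class
signal**: the features are uninformative about the label by construction.
Any performance of the correct arm above chance would be a bug, and any
excess of the pitfall arm over the correct arm is pure leakage.  The correct
arm is held to this by comparison with an explicit chance model (below).

### Classifier

The default classifier for the leakage experiments is 1-nearest-neighbour
after per-feature standardization with training-set statistics.  A
memorization classifier makes duplicate and near-duplicate leakage maximally
visible, which is the phenomenon under study; random-forest and logistic
alternatives are provided for robustness checks.  The validation subset is
created (60/20/20 by default) but deliberately unused: no hyperparameter is
tuned, so the three-way split structure is preserved without adding tuning
noise.

### Chance level

"Chance" for an F1 score depends on the class balance of the test set and on
the rate at which a label-blind classifier emits positives.  The package
estimates it by Monte Carlo: a predictor that outputs positives with
probability *q* independently of the truth, scored on test sets with exactly
the class composition each repetition realized.  For *q* we use the positive
fraction among *distinct* (unique-provenance) training rows — duplicating or
jittering a minority row does not move a nearest-neighbour decision
boundary, so class rebalancing by duplication does not change the rate at
which such a classifier predicts the minority class.  An honest correct arm
should match this chance level to within sampling error (the suite uses
3 standard errors of the correct arm's mean).

### Degenerate repetitions

A split that leaves a single-class training set or a positive-free test set
makes F1 meaningless; such repetitions are redrawn with a fresh derived seed,
up to 10 times, then raised as an error.  At the default sample sizes
redraws are rare (≈10 % of repetitions for the 10 %-prevalence oversampling
data, negligible elsewhere) and affect both arms identically.

### Null calibration

Running the harness with identical policies in both arms yields identical
arms — the pairing shares data, split and classifier seeds — so the Wilcoxon
comparison never rejects and the harness cannot manufacture an effect out of
its own plumbing.  The calibration of the rank-sum test itself against
small-sample exactness is established separately (below).

## Synthetic data generators

All feature noise is standard Gaussian; "signals" are mean shifts along
fixed random unit directions in feature space.  Each config carries one
master seed; all sub-streams (labels, noise, directions, geometry) derive
from it by fixed offsets, so equal configs reproduce bitwise-identical data.
Positive-class counts are exact: `round(class_fraction · n)`.

* **Tabular** (`gen_tabular`) — one row per patient, emulating a
  radiomics-style feature table.  Defaults: 100 patients, 10 features;
  10 % positive prevalence in the oversampling experiment, balanced
  elsewhere; 1000 features with the top 10 kept in the feature-selection
  experiment (a high-dimensional screen over a small cohort, where
  selection bias is classically largest); `signal_strength = 0`.
* **Patient patches** (`gen_patient_patches`) — 20 patients × 30 rows with a
  per-patient signature offset drawn once per patient from a Gaussian of SD
  3 and added to all of that patient's rows.  This mimics patches of one
  slide or scan sharing acquisition characteristics: rows of one patient are
  far closer to each other than to other patients' rows, so a row-level
  split lets a memorizing model recognise the patient rather than the class.
* **CT volumes** (`gen_ct_volume`) — ellipsoid geometry only: a soft-tissue
  body ellipsoid in exterior air, two air-filled lung ellipsoids, an airway
  tube on the midline and a bowel-gas pocket low in the body.  No anatomical
  realism is attempted; only Hounsfield-unit contrast and connectivity
  topology matter for the thresholding baseline.  Intensities: tissue
  40 ± 20 HU, air −1000 ± 30 HU, noise clipped at ±5 SD, so the two classes
  are separated from the −400 HU air threshold by far more than 3 SD on
  either side and the generator is exactly self-consistent with the
  threshold.  Non-lung internal air is sized as a fraction of the lung
  volume (defaults: airway 5 %, bowel gas 8 %), which gives the internal-air
  proxy a closed-form Dice of 2L/(2L+E) against the lung truth.  The
  default grid is 48³ voxels at 2 mm spacing — coarse, but sufficient for
  exact mask algebra.  The 10-volume evaluation cohort draws the total
  extra-air fraction uniformly from [0.08, 0.26] per volume (split 40/60
  airway/bowel), spreading proxy Dice scores over ≈0.89–0.96.
* **Batch data** (`gen_batch_dataset`) — 500 samples per source; source A
  contributes only class 0, source B only class 1, each adding its signature
  offset (magnitude 3) to the features.  The two signature directions are
  orthogonalised so the parameter induces a fixed centroid separation of
  3·√2 rather than a seed-dependent one.  The external set holds class-0
  samples with source B's signature: exactly the case of healthy pediatric
  radiographs confronting a model that learned "pediatric = pneumonia".
  The default batch classifier is logistic regression — the analogue of a
  flexible model keying on a global acquisition signature, which
  nearest-neighbour would dilute with feature noise.
* **Slides** (`gen_synthetic_slide`) — tissue-coloured disks (base RGB
  ≈ (168, 96, 156), per-blob and per-pixel jitter, channels capped at 205)
  stamped on a near-white (245, 245, 245) background until the requested
  foreground fraction is covered.  Foreground and background are separable
  by mean-channel luminance at 0.8 of full brightness by construction.

## Performance indicators

Accuracy, precision, recall and F1 come from exact confusion counts; F1 is
computed on the positive (minority) class.  Zero-denominator metrics are
reported as NaN with an `undefined` flag and enter aggregates as 0 with a
warning — the conservative convention for a classifier that never predicts,
or never encounters, the positive class.  `majority_accuracy` gives the
always-majority baseline that makes raw accuracy meaningless under
imbalance.

Dice = 2|X∩Y|/(|X|+|Y|) and IoU = |X∩Y|/|X∪Y| use the convention that two
empty masks overlap perfectly (both scores 1).  The algebraic identity
Dice = 2·IoU/(1+IoU) (hence Dice ≥ IoU, with equality only at 0 and 1) is
property-tested exactly, in integer arithmetic, and holds for every
evaluation the package reports: a Dice of 0.94 is the same measurement as an
IoU of 0.88.

The Wilcoxon rank-sum test is implemented in the package (not delegated) so
its behaviour is fully specified and testable: midranks for ties, and a
two-sided p-value that is the *exact* permutation probability whenever the
number of group assignments C(n, n₁) is at most 500 (covering all pairs with
n₁+n₂ ≤ 10), falling back to the normal approximation with tie correction
and a 0.5 continuity correction otherwise.  The reported statistic is always
the standardized z of the first sample's rank sum.  The small-sample path is
validated against an independent enumeration oracle; the pure normal
approximation can err by up to ≈0.11 in p at the smallest sizes (e.g.
n₁ = 1, n₂ = 4), which is why the exact path exists.

## Segmentation baseline

`baseline_lung_proxy` marks every voxel strictly below −400 HU as air
(−400.0 itself is excluded) and removes air components connected to any face
of the grid (default face connectivity, 6; 26 available), operationalising
"air outside the body" without any geometric modelling.  On the synthetic
cohort the result equals the internal-air truth voxel for voxel, so every
prediction provably contains the trachea and bowel gas — anatomically wrong
masks — while mean Dice against the lung truth is ≈0.92.  This is the
baseline argument: a sophisticated lung segmenter that does not clearly beat
this number has demonstrated nothing.

## Patch extraction

Slides are downscaled by block averaging (default ×4, truncating incomplete
blocks), foreground is taken as mean-channel luminance < 0.8 of full
brightness, and square patches (default 1024 px, scaled down to 16–64 px in
tests and demos) are sampled at uniformly random origins from the downscaled
image.  A candidate with ≥ 75 % background is rejected (exactly 75 % is
rejected); sampling stops at 200 accepted patches per image or after
50 attempts per requested patch, a short count being a valid, logged
outcome.  Candidate origins are drawn with replacement; duplicate origins
are allowed and vanishingly rare on large images.

## Problem sizes and runtime

The default study conditions — 100 repetitions per paired experiment on
100-patient tables (600-row patch tables), 200 meta-repetitions of 20 for
the null calibration, 10 volumes of 48³ voxels, and 110 synthetic slides of
256² pixels for the 22 000-patch extraction run — were chosen so the entire
experiment battery completes in well under a minute of CPU time apiece,
making every phenomenon reproducible interactively.

## Limitations

* The generators emulate statistical structure (imbalance, within-patient
  correlation, source confounding, HU contrast, foreground/background
  separability), not the appearance, texture or physics of medical images.
  Passing results show that the *pipeline mechanics* create or remove the
  inflation; they say nothing about effect sizes on any real dataset, which
  depend on dataset, features and model capacity.
* Leakage effect sizes here are classifier-dependent: 1-NN is close to a
  worst case for duplicate leakage; smoother models would show smaller (but
  directionally identical) inflation.  The feature-selection effect in
  particular is a mean-level effect — strongly significant over 100
  repetitions, but noisy repetition by repetition.
* Lightweight tabular classifiers stand in for deep networks; image-domain
  training is out of scope.
* Volumes are ellipsoid compositions; the internal-air/lung Dice is
  controlled analytically rather than anatomically.
* Real-volume input is NIfTI only; DICOM is out of scope.
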