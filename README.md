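# mlpitfalls

Desk-scale, fully reproducible demonstrations of three methodological
pitfalls that inflate the apparent performance of machine-learning models in
medical image analysis:

1. **Data leakage** — violating the independence of training and test data
   by oversampling, augmenting, or selecting features *before* splitting, or
   by scattering a patient's data points across subsets;
2. **Misleading indicators and baselines** — accuracy on imbalanced data,
   and Dice/IoU scores quoted without a trivial baseline for comparison;
3. **Batch effects** — class labels confounded with the acquisition source,
   so the model learns the scanner, not the disease.

The package is aimed at researchers and reviewers who want to *show* these
failure modes rather than argue about them: every phenomenon is generated
from synthetic data with known structure, runs in seconds on one CPU, and is
paired with the correct procedure that makes the inflation vanish.

## The core quantities

For binary classification with confusion counts TP, FP, FN, TN:

- precision P = TP/(TP+FP), recall R = TP/(TP+FN), F1 = 2PR/(P+R),
  accuracy = (TP+TN)/n.  A naive always-majority predictor achieves
  accuracy = max class frequency (94 % at 6 % prevalence) with recall 0 —
  which is why accuracy alone is meaningless under imbalance.

For two segmentation masks X and Y:

- Dice(X,Y) = 2|X∩Y| / (|X|+|Y|),  IoU(X,Y) = |X∩Y| / |X∪Y|,
  related exactly by **Dice = 2·IoU/(1+IoU)**, so Dice ≥ IoU always.

Paired pitfall-vs-correct pipelines are compared over 100 repetitions with a
two-sided Wilcoxon rank-sum test (exact permutation p for small samples,
tie- and continuity-corrected normal approximation otherwise).

Because every synthetic generator default carries **zero class signal**, the
correct pipeline can only score at chance — so whatever the leak-prone
pipeline gains over it is leakage, isolated and measurable.

## Worked example

Run the oversampling experiment: two identical 1-nearest-neighbour pipelines
on the same imbalanced, label-independent feature tables (100 patients, 10 %
positive), differing only in whether class balancing happens before or after
the train/validation/test split.

```bash
mlpitfalls run oversampling --out-dir results --seed 0 --repetitions 100
```

```
INFO mlpitfalls: oversampling: delta mean F1=0.8175, Wilcoxon z=12.63 p=1.49e-36
```

`results/oversampling_summary.json` (abridged):

```json
[
  {"arm": "pitfall", "mean_f1": 0.9161, "sd_f1": 0.0560},
  {"arm": "correct", "mean_f1": 0.0986, "sd_f1": 0.2084}
]
```

Read: oversampling **before** the split copies minority rows into both
training and test sets; a memorizing classifier then "recognises" its test
samples and reports a mean F1 of 0.92 on pure noise.  The identical pipeline
with oversampling applied only to the training set scores 0.10 — the chance
level for this class balance.  The gap (0.82, Wilcoxon p ≈ 1e-36) is
entirely leakage.  `mlpitfalls run` also writes per-repetition metrics CSV
and a manifest; `augmentation`, `patient-split`, `feature-selection` and
`batch-effect` work the same way.

The segmentation baseline tells the complementary story — a high Dice score
with anatomically wrong masks:

```bash
mlpitfalls segment-baseline --synthetic 10 --out-dir results --seed 0
```

```
INFO mlpitfalls: baseline proxy: mean Dice=0.9060 mean IoU=0.8288 over 10 volumes
```

Every one of those predictions provably contains trachea and bowel-gas
voxels; thresholding air below −400 HU and discarding the air outside the
body is not a lung segmenter, yet it scores a mean Dice of 0.91.  Any real
model must beat this baseline before its Dice means anything.

A whole-slide-style patch-extraction pipeline (downscale, colour-threshold
foreground, random patches, ≥75 %-background exclusion, 200-patch cap) is
available as `mlpitfalls extract-patches`; the library API under
`mlpitfalls.*` exposes all generators, splitters, metrics and experiment
runners directly.

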