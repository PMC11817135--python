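# actimage

Wrist-actigraphy day-images and a small 2D convolutional network for
three-way classification of **control**, **depression** and **schizophrenia**
from per-minute motor-activity counts.

Actigraphy — continuous wrist-worn accelerometry reported as nonnegative
per-minute activity counts — carries diagnostic signal for mood and
psychotic disorders: depressed subjects tend to move least, while the
schizophrenia cohorts this pipeline targets show the highest overall motor
activity. `actimage` implements the full pipeline from raw recordings to an
evaluated classifier:

1. **I/O** — readers/writers for the public Depresjon/PSYKOSE CSV dialect
   (`timestamp,date,activity` at one-minute cadence), cadence validation,
   subject metadata and cohort summary tables.
2. **Encoding** — each complete midnight-to-midnight day (1440 minutes)
   is min-max rescaled to [0, 255],

   x'ᵢ = Min + (xᵢ − min(x)) · (Max − Min) / (max(x) − min(x)),

   reshaped row-major into a 30 × 48 grayscale image, and z-normalized
   (zᵢ = (xᵢ − x̄)/σ, population σ) at model-input time. Labels:
   control 0, depression 1, schizophrenia 2.
3. **Model** — a compact 2D CNN written in NumPy (forward and backward):
   three blocks of [conv 48 × 3 × 3 (valid) → ReLU → max-pool 3 × 3 stride 2]
   then dense 900 → 300 → 100 → 3 with ReLU + dropout and a softmax head;
   trained with Adam on categorical cross-entropy. Shape trace:
   30×48 → 28×46 → 13×22 → 11×20 → 5×9 → 3×7 → 1×3 → flatten 144.
4. **Protocol** — stratified 70/30 split (floor + largest remainder, so 70%
   of 1436 images is exactly 1005), k-fold cross-validation (k = 3) with
   loss/accuracy curve capture and an underfit check, then a blind test of
   the held-out 30% reporting the confusion matrix, per-class
   precision/recall/F1 (one-vs-rest), overall accuracy, inference time and
   peak memory.
5. **Synthetic cohorts** — a seedable generator of realistic actigraphy
   (cosinor circadian rhythm, gamma-Poisson overdispersed counts,
   zero-inflation, between-subject variability) with condition profiles
   encoding the depression < control < schizophrenia activity ordering, so
   the whole pipeline is testable without downloading clinical data.

## Worked example

```bash
actimage simulate --out cohort/ --preset easy --subjects 10 --days 8 --seed 7
actimage encode --data cohort/ --out dataset.csv
actimage train --dataset dataset.csv --out run/ --epochs 30 --dropout 0.2 --k 3 --seed 7
actimage evaluate --run run/
```

which prints:

```
wrote 30 subjects under cohort
240 images (labels 0/1/2: 80/80/80) -> dataset.csv
fold 1: accuracy 0.82 (overfit-suspect)
fold 2: accuracy 0.96 (acceptable)
fold 3: accuracy 0.93 (overfit-suspect)
mean CV accuracy 0.90; run artifacts in run
| Diagnostic | Precision | Recall | F1-Score |
|---|---|---|---|
| Control | 0.96 | 1.00 | 0.98 |
| Depression | 1.00 | 0.96 | 0.98 |
| Schizophrenia | 1.00 | 1.00 | 1.00 |
| Accuracy |  |  | 0.99 |
inference 0.035 s/batch, peak memory 236.3 MB
```

Per-fold accuracies are validation accuracies inside the cross-validation;
the parenthetical is the train-vs-validation loss verdict (the validation
convention flags a validation loss clearly below training as underfitting
and clearly above as suspected overfitting). The final table is the blind
test of the untouched 30% (72 images here): one row of one-vs-rest
precision/recall/F1 per diagnosis, and the overall accuracy (diagonal
fraction of the confusion matrix) as footer. Timing and memory are measured
on your machine and will differ. `--dropout 0.2` suits this short 30-epoch
schedule; the architecture's default of 0.5 expects the full 100-epoch
protocol. At larger scale (60 subjects / 600 images, the library-level
experiment in `actimage.experiments`) the easy preset is recovered with mean
cross-validation accuracy above 0.95.

The same workflow runs on real Depresjon/PSYKOSE-style data: point
`encode --data` at a directory with `control/`, `depression/` and
`schizophrenia/` subdirectories of per-subject CSVs.

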