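# fhpdetect

Non-contact screening for **forward head posture (FHP)** — the anterior
carriage of the head relative to the trunk that is common in adolescents and
associated with neck pain, muscle imbalance and restricted cervical motion —
from 2-D body landmarks detected in a lateral photograph.

The package is aimed at researchers and clinical engineers who have
pose-estimator output (OpenPose-style keypoint JSON or flat landmark tables)
plus basic demographics, and want a reproducible pipeline from raw keypoints
to a validated binary FHP classifier with exact confidence intervals.  Because
clinical posture images are rarely shareable, the package also ships a
synthetic cohort generator with a known Bayes-optimal accuracy, so the whole
pipeline can be exercised, benchmarked and regression-tested without any
patient data.

## Method

From the four anatomical points in a right-side view — right acromion (RAP,
the vertex), nasal point (NP), right pupil centre (RPCP) and right external
auditory meatus (REAMP) — seven geometric features are computed:

* **NAH, PAH, EAH** — unsigned angles between the shoulder→nose /
  shoulder→eye / shoulder→ear segments and the horizontal line through the
  shoulder, each obtained from the cosine rule
  `cos A = (b² + c² − a²) / 2bc` on the right triangle formed with the foot
  of the perpendicular; range [0°, 90°].
* **ENA** — the angle at the shoulder between the ear and nose segments,
  range [0°, 180°].
* **d1, d2, d3** — vertical (image-row) distances of nose, eye and ear above
  the shoulder, in pixels.

FHP flattens the head forward, so affected subjects show systematically
*smaller* angles.  Together with five demographics (gender, age, height,
weight, BMI) these form a 12-feature universe.

Feature subsets are selected by a **genetic-algorithm wrapper**: binary
chromosomes `x ∈ {0,1}^P` evolve under tournament selection, single-point
crossover, per-bit mutation and elitism, scored by

    f(x) = C · ( Σᵢ N(xᵢ)/P + (log m − log n) ) / k

where `k` is the subset size, `N(xᵢ)` the (normalised) frequency with which
feature *i* has appeared in chromosomes evaluated so far, and `m` of `n`
reference-class training subjects are predicted correctly by the wrapped
classifier under seeded stratified inner cross-validation.  Selection is run
per candidate model — extremely randomized trees (ETC), gradient boosting
(GBC) and extreme gradient boosting (XGB) — and the winner is the
(model, subset) pair with the best outer-CV accuracy.

Class imbalance is handled by minority-class oversampling (inside training
folds only, by default), evaluation uses stratified 10-fold CV plus a
stratified 90/10 hold-out, and every reported proportion (accuracy,
sensitivity, specificity, PPV, NPV) carries an **exact Clopper–Pearson 95%
interval** from the beta-quantile characterisation.  A companion routine
reconstructs the integer confusion matrix consistent with rounded published
percentages, which pins down exact counts from a results table.

## Worked example

```bash
fhp run --config examples/demo.yaml
```

simulates a 200-subject cohort (62% FHP prevalence), extracts features, ranks
the three ensembles by 5-fold CV, GA-selects features, trains the winner on a
stratified 90/10 split and prints the held-out evaluation:

```json
{
 "confusion": {"FN": 3, "FP": 2, "TN": 6, "TP": 9},
 "metrics": {
  "accuracy":    {"estimate": 0.75,  "lower": 0.509, "upper": 0.913, "k": 15, "n": 20},
  "sensitivity": {"estimate": 0.75,  "lower": 0.428, "upper": 0.945, "k": 9,  "n": 12},
  "specificity": {"estimate": 0.75,  "lower": 0.349, "upper": 0.968, "k": 6,  "n": 8},
  "ppv":         {"estimate": 0.818, "lower": 0.482, "upper": 0.977, "k": 9,  "n": 11},
  "npv":         {"estimate": 0.667, "lower": 0.299, "upper": 0.925, "k": 6,  "n": 9}
 }
}
```

(values abridged to three decimals): of the 20 held-out subjects, 15 were
classified correctly; 9 of the 12 true FHP cases were caught (sensitivity
0.75) and 6 of 8 normals were cleared (specificity 0.75).  The wide exact
intervals are the honest price of a 20-subject test set.  The full run
report, the GA history and the ablation table are written to `fhp_demo_run/`.

The same stages are available individually (`fhp simulate`, `fhp extract`,
`fhp select`, `fhp train`, `fhp predict`, `fhp evaluate`, `fhp ablate`) and
as library functions (`fhpdetect.features`, `fhpdetect.ga_select`,
`fhpdetect.classify`, `fhpdetect.evaluate`, `fhpdetect.synth_cohort`).

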