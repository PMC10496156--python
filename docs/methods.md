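# Methods

## Geometry

All posture features derive from four anatomical points in a right-side
view: right acromion (RAP), nasal point (NP), right pupil centre (RPCP,
taken as the right-eye keypoint — the 18-keypoint layout has no finer
landmark) and right external auditory meatus (REAMP, the right-ear
keypoint).  Angles are *unsigned*: the three horizontal angles (NAH, PAH,
EAH) live in [0°, 90°] by construction of the foot-of-perpendicular
triangle, ENA in [0°, 180°].  Image coordinates use the image convention
(origin top-left, y down); all results are invariant to translation and to
mirroring in x, and the pixel distances d1–d3 scale linearly with image
scale.  Whether a clinical protocol would sign the angle when the nose
falls below the shoulder row is undecidable from geometry alone; the
unsigned convention is a deliberate choice and is stated in the API docs.

Numerics: the cosine-rule angle is never evaluated as `arccos` of the raw
cosine.  Where only side lengths are available the algebraically identical
half-angle form `tan(A/2) = sqrt((a²−(b−c)²)/((b+c)²−a²))` is used
(needle-triangle safe; negative radicands from round-off are clamped to
zero, the analogue of clamping the cosine to [−1, 1] with tolerance 1e-9).
Where coordinates are available the exact identity
`b²+c²−a² = 2(p−v)·(q−v)` reduces the cosine rule to
`atan2(|cross|, dot)`, which is well-conditioned everywhere.  Three rounded
side lengths alone determine a needle-triangle angle only to ~1e-9 degrees,
so the coordinate route is the default inside `compute_features`.

Degenerate inputs raise typed errors naming the offending feature or
anatomical point; a missing or low-confidence keypoint (detector
confidence below `conf_min`, default 0.3; the zero-confidence triplet is
the standard missing-point convention) raises an incomplete-landmarks
error listing the missing points, and the pipeline's extraction stage
skips and logs such subjects.

## GA wrapper feature selection

Chromosomes are binary inclusion masks over the 12 features; the GA
maximises

    f(x) = C · ( Σ_{i∈x} N(x_i)/P + perf ) / k

with `k` the subset size and `P = 12`.  Four points in this formula are
genuinely open to interpretation, and the package fixes them as its own
design choices:

* **Orientation.** `perf = log m − log n` (``accuracy_rewarding``,
  default) so that subsets whose wrapped model recovers more
  reference-class subjects score higher.  The literal printed form
  `log n − log m` rewards *mis*classification and is retained behind
  ``orientation="paper_literal"`` for fidelity experiments.
* **Counter normalisation.** `N(x_i)` is the inclusion *frequency* of
  feature i over all chromosomes evaluated so far (count divided by
  evaluations), bounding the term in [0, 1] and keeping it commensurate
  with the log-performance term at any run length — consistent with C's
  role of limiting the fitness.  Raw counts grow without bound, drown the
  performance signal within a few generations and collapse selection onto
  a single most-frequent feature; they remain available via
  ``counter_mode="count"``, as does a per-generation reset
  (``counter_scope="generation"``).
* **Reference class.** `m`/`n` count the *normal* (minority) class by
  default.  Because training folds are balanced by oversampling, noisy
  subsets drift toward predicting the majority (FHP) class, so
  majority-class recall actually rewards uninformative features;
  minority-class recall (specificity) degrades sharply when informative
  features are missing and is the discriminating signal.  Configurable.
* **m measured honestly.** `m` is pooled over held-out folds of a seeded
  stratified inner cross-validation (5-fold default) of the wrapped model
  on the masked columns — never on the data the model trained on, where
  tree ensembles would score `m = n` for any mask.

GA defaults: population 50, 40 generations, crossover 0.8, per-bit
mutation `2/P`, tournament size 3, elitism 2.  The doubled mutation rate
(vs the canonical `1/P`) measurably improves re-introduction of dropped
informative features against the frequency-feedback lock-in; elites carry
their recorded fitness unchanged, which makes the per-generation best
fitness non-decreasing even though the frequency term evolves.  Fitness
evaluations are cached by mask (the classifier trains once per distinct
subset); the frequency counters advance on every evaluation request,
cached or not, so caching does not perturb the dynamics.  `m = 0` yields
the worst representable fitness instead of a crash.  Ties between
candidate models are broken by list order, and identical specs under one
seed produce identical masks.

A known behaviour, not a bug: with `perf ≤ 0`, dividing by `k` means that
dropping *any* feature amplifies the performance penalty, so selected
masks tend to retain several neutral features alongside the informative
ones.  The selection guarantee exercised by the tests is therefore
*recovery* (the informative features are included) and *no harm* (selected
subset matches all-features accuracy within 2 points), not minimality.

## Classification and evaluation

Candidate families: extremely randomized trees, gradient boosting and
extreme gradient boosting, seed-pinned, single-threaded, library-default
hyperparameters unless a run config overrides them.  Oversampling
duplicates minority rows (with replacement, seeded) until parity; by
default it happens inside each training fold and on the training side of
the hold-out split only, so duplicated rows never leak into evaluation
data; a ``pre_split`` mode balancing the whole table first exists for
protocol-fidelity comparisons.  Splits and folds are stratified by label;
the hold-out fraction is 0.10 (an integer test-set size, rounded, so 1651
subjects give exactly 165).

Each screening metric is an exact binomial proportion `k/n`;
Clopper–Pearson 95% bounds come from beta quantiles
(`Beta(k, n−k+1)` / `Beta(k+1, n−k)`, with the closed-form 0/1 endpoints).
Published-style percentages are rounded half-away-from-zero to one
decimal; the confusion-matrix reconstruction searches exhaustively over
`TP × TN` for matrices whose accuracy/sensitivity/specificity round to the
given values (PPV/NPV are then determined) and returns them TP-ascending.
The ablation harness scores one model spec under several named feature
sets on a shared stratified split, training-side oversampled, test side at
natural prevalence.

## Synthetic cohort

The generator emulates the study conditions the pipeline targets: cohort
size 1651 with FHP prevalence 1024/1651, demographics per class matching
the published cohort table (age ≈ 12.1 ± 1.2 years truncated to [10, 15],
height 160.38 ± 9.22 vs 158.18 ± 11.09 cm, mass 55.48 ± 16.16 vs
54.18 ± 15.43 kg, ~53% female in both classes), and side-view landmark
files in the standard 18-keypoint JSON dialect.

Head geometry is driven by three class-conditional truncated-Gaussian
latents: the ear elevation EAH, the ear–nose separation ENA and an
eye–nose offset.  Nose and eye elevations follow as `NAH = EAH + ENA` and
`PAH = NAH + offset`; in 2-D the angle between two rays from the shoulder
*is* the difference of their elevations, so a single parameter controls
both the ENA distribution and the NAH−EAH gap, and the ear < nose < eye
elevation ordering holds by construction.  Infeasible draws
(`PAH ≥ 88°`) are rejected and resampled (bounded retries).

The real cohort's angle distributions are unpublished, so the
class-conditional defaults are the package's own calibration, chosen once:
normal EAH 55 ± 6°, ENA 14 ± 4°, offset 5 ± 2°; FHP 47 ± 6°, 11 ± 4°,
4 ± 2° — FHP smaller in every angle, giving a closed-form Bayes-optimal
accuracy of 0.80 at the study prevalence: clearly learnable, far from
separable, and well above the 62% majority rate.

The *vertical* head heights (which become d1–d3 exactly) are drawn from
class-independent distributions and each ray's length is back-solved as
height/sin(elevation): forward head posture displaces the head anteriorly
at similar vertical height.  Consequently the four angles are the only
informative features in the 12-feature universe — the planted ground truth
for the selection benchmarks — while d1–d3 and the demographics are
realistic but (near-)uninformative.  Landmark noise is isotropic Gaussian
(1.5 px default), detector confidences Beta(8, 2), and per-keypoint
dropout is off by default.  The remaining 14 keypoints are a static
skeleton template plus noise so emitted files are format-complete.

`bayes_accuracy` evaluates the closed form
`π Φ(d/2 + t/d) + (1−π) Φ(d/2 − t/d)` with `t = log(π/(1−π))` and `d` the
Mahalanobis separation of the three latents (per-class SDs pooled when
unequal; latent truncation, landmark noise and the faint demographic
signal are ignored — each shifts the ceiling by well under one point).

What passing tests on this cohort do **not** show: robustness to real
pose-estimator failure modes (correlated, pose-dependent landmark error;
left/right confusion; occlusion), to uncontrolled camera geometry, or to
demographic distributions beyond the emulated adolescent cohort.  The
generator is a benchmark with known truth, not a substitute for clinical
validation.

## Problem sizes in tests and the acceptance script

Statistical checks use cohorts of 240–800 subjects; the selection
benchmark runs the GA at population 40 × 25 generations with a 12-tree
extremely-randomized-trees wrapper on ten 500-subject cohorts (about nine
minutes on one CPU); the Bayes-ceiling benchmark uses 800 subjects and
default 100-tree ensembles.  The demonstration pipeline config uses 200
subjects with reduced tree counts so a full end-to-end run finishes in
seconds.  All randomness flows from explicit seeds; reports embed the seed
and a hash of the generating configuration, and rerunning any stage with
the same configuration is byte-identical.

## Known limitations

* The fitness's size penalty is structurally weak under the
  accuracy-rewarding orientation (see above); selected subsets are
  supersets of the informative features rather than minimal sets.
* The 18-keypoint layout has no seventh-cervical-vertebra landmark, so the
  clinical craniovertebral angle cannot be computed; the shoulder-vertex
  angles are analogues, not replacements.
* Angles are unsigned; a subject whose nose sits below the shoulder row
  (not observed in practice) would alias onto a positive angle.
* The exact binomial interval is conservative (coverage ≥ nominal), so
  reported intervals are, if anything, slightly wide.
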