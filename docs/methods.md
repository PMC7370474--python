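# Methods

`pheoihd` re-implements, as a tested pipeline, a data-mining procedure for
predicting intraoperative hemodynamic instability (IHD) during
pheochromocytoma resection: Relief-F feature weighting with threshold
retention, a multi-scheme classifier benchmark, a balanced random-forest
(BRF) ensemble for the 1:2.82 class imbalance, confusion-matrix/ROC
assessment, and a three-list importance consensus that names the final risk
factors. The clinical dataset behind the original analysis is not public, so
a synthetic-cohort generator reproducing its published class-conditional
summary statistics stands in for it; everything downstream is exercised and
validated on those synthetic cohorts plus the published summary tables
themselves (shipped as fixtures).

## Synthetic cohort generator

The generator (`pheoihd.cohort`) draws a binary IHD label from
Bernoulli(74/283) and then each of 18 predictors from its class-conditional
distribution, transcribed into `data/population_specs.yaml`:

- **Normal** for variables reported mean ± SD (age, BMI, tumor size,
  enhanced-CT difference). BMI and tumor size are truncated at > 0 for
  physical plausibility (values outside support are redrawn, with a bounded
  retry count so a zero-mass support errors out rather than spinning).
- **Lognormal** for the skewed 24-h urine vanillylmandelic-acid/upper-limit
  ratio (`prevma`), reported as median (IQR). The fit anchors the median
  exactly (μ = ln median) and takes σ from the log-IQR width,
  σ = (ln q₃ − ln q₁)/(2·z₀.₇₅). A two-parameter lognormal cannot match
  both quartiles exactly unless they are log-symmetric about the median;
  the fit preserves the median and the log-IQR width exactly and
  compromises the individual quartiles by ≲ 1% for the reported values.
- **Bernoulli** for binary traits (sex, comorbidities, preparation items,
  tumor side, approach), with the reported per-class percentages.
- **Ordered categorical** for the ASA score (1–3) and the hypertension grade
  (0/1/2). Reported percentages are renormalized on load when rounding
  makes them sum to 99.9% instead of 100%.

Features are sampled independently given class: the source tables publish
no correlation structure, so none is imposed. The crystal-fluid and
colloid-fluid indicators were reported jointly in the source population
table; both binary columns therefore carry the same class rates. ASA and
hypertension carry an encoding flag (`categorical` one-hot expands them,
`numerical` keeps the integer code), reproducing the two dataset variants
the original benchmark compared; the defaults follow the source description
(ASA categorical, hypertension numerical) and a single mode switch flips
both.

**What passing tests show, and what they do not.** Round-trip tests confirm
that sampling 10⁵ patients and summarizing recovers every configured
parameter within sampling error (z-scores against analytic standard errors;
with ~170 simultaneous comparisons we require ≥ 98% within 3 SE and all
within 5 SE, since a literal all-within-3-SE criterion would fail by chance
alone about half the time). This validates the generator against the
published marginals only. Real clinical data have inter-feature
correlations (tumor size with CT difference, BMI with comorbidity), which
independence-given-class discards — so synthetic discrimination performance
(AUC ≈ 0.7 at the study's sample size) is expected to undershoot the
original report, and nothing here certifies performance on real patients.

## Relief-F

`pheoihd.relief` implements the multi-class Relief-F update: for each
reference patient R, the k nearest same-class neighbours (hits) and k
nearest other-class neighbours (misses) are found under a Manhattan
distance on per-feature diffs, and each feature's weight is decremented by
hit diffs and incremented by prior-weighted miss diffs, normalized by m·k.
The per-feature diff is an identity mismatch (0/1) for nominal features and
a range-normalized absolute difference for continuous/ordinal ones, with an
ε-guard for constant columns. Defaults: m = all rows, k = 10 capped at
(smallest class − 1), ties among equidistant neighbours broken by position
in a seeded shuffle so results are reproducible from one seed.

Normalized weights live in [−1, 1]; the published weight table for the
original cohort is on a different (unnormalized, unrecoverable) scale, so
it ships as a fixture (`data/relief_weights_reference.csv`) used only for
ordering-dependent operations: cutting at the published −24 threshold
(retaining 10 of 18 features) and taking top-k lists. The weight table
returned by the implementation carries both the normalized weight and the
raw accumulated sum. Note that the −24 default cutoff, applied to the
normalized scale of a synthetic cohort, retains all features — the
threshold is meaningful only on the scale it was published for; on
synthetic runs, selection is effectively configured via the cutoff value.

## Validation schemes and benchmark

`pheoihd.splits` realizes the three validation families at the studied
settings (nine schemes): hold-out at 80/20, 70/30, 60/40 with train size
⌊n·frac⌋ (this floor convention reproduces the 114-patient test set of the
60/40 split of 283), stratified by largest-remainder rounding per class;
k-fold CV at 5, 10, 15 folds, stratified, with per-class remainders
assigned greedily to the smallest folds so total fold sizes differ by at
most one; and bootstrap subsets of 50, 100, 200 — train drawn with
replacement, test drawn from the never-sampled pool (guaranteeing
disjointness), 10 repeats per setting. Stratification defaults on (the
26% prevalence makes unstratified splits noisy) with a switch off.

The seven-model roster delegates to scikit-learn: logistic regression,
Gaussian naive Bayes, a Gini tree (CART-like), an entropy tree (C4.5-like),
a cost-complexity-pruned entropy tree standing in for the proprietary C5.0,
AdaBoost over shallow entropy trees standing in for boosted C5.0, and a
100-tree random forest. Per benchmark cell (classifier × scheme), accuracy
and AUC are unweighted means over the scheme's train/test parts; every
cell's plan and fit seeds are logged, and a failing classifier marks only
its own cell as failed.

## Balanced random forest

`pheoihd.brf` implements the imbalance-aware ensemble: split rows by class,
draw n rows with replacement from each class (n defaults to the minority
size of the training portion), train a random forest on the 2n balanced
rows, repeat for m = 21 voters (odd to reduce ties; 100 trees per forest,
√p features per split — all configurable), and classify by the sign of the
summed ±1 forest votes with minority = +1. A zero vote sum resolves to the
minority class: conservative toward the rare, clinically dangerous outcome.
For ROC construction a separate score path averages the forests' estimated
minority-class probabilities.

Evaluation uses one global held-out test set carved before any training
(rather than a per-voter leave-out), which prevents leakage into the
ensemble vote; each voter's out-of-bag rows — training rows absent from its
balanced bootstrap — are kept for permutation importance. Audit multisets
of every voter's training rows are retained on the model and asserted
balanced in tests. On synthetic 1:2.82 cohorts the balanced ensemble's
minority-class recall exceeds a plain forest's in ≥ 80% of seeded
repetitions (a statistical acceptance mirroring the method's motivation),
and predictions are stable in m (≤ 2% disagreement between m = 50 and
m = 100 on a fixed test set).

## Assessment

`pheoihd.metrics` preserves the source convention that the *positive* class
is y = 0, the patients without IHD; the meaning travels inside the
`ConfusionMatrix` so it cannot silently invert, and a flag flips it.
Metrics follow the printed formulas exactly; a zero denominator yields a
flagged NaN, never a silent zero. The ROC places a threshold at every
distinct score, groups ties into single steps, and its trapezoidal area
equals the Mann–Whitney pairwise probability (ties ½) — property-tested
against an O(n²) oracle on all small instances and cross-checked against
scikit-learn. Interval estimates use a percentile bootstrap over test rows
(2000 replicates by default; single-class resamples are skipped and more
than 20% of them is an error). Bootstrap coverage was verified by
simulation at n = 200 against a band of [0.90, 0.99] around the nominal
95% — percentile bootstrap is known to undercover slightly for AUC at
moderate n. Reported metrics are rounded to 4 decimals; full precision is
retained internally.

## Importance and consensus

MDA permutes one feature at a time on each voter's out-of-bag rows and
averages the accuracy drop over permutations (10 by default) and voters,
reported in percent points. MDG walks every tree and sums node-weighted
Gini impurity decreases per feature (normalized by root weight), averaged
over trees and voters; it is nonnegative and conserves the ensemble's total
impurity decrease. The consensus rule takes the top k = 5 of the MDA, MDG
and Relief-F rankings and keeps features present in at least 2 of the 3
lists (min_lists is configurable; the stricter all-3 reading is available
but does not reproduce the published five-predictor set, which the default
does exactly: BMI, tumor size, urine VMA ratio, CT difference, age).
Output order: number of supporting lists, then best rank, then rank sum,
then name.

## Pipeline

`pheoihd.pipeline` chains the stages (cohort → Relief-F → benchmark → BRF on
a stratified 60/40 holdout → importance consensus) under a single global
seed fanned out per stage via SHA-256, so one integer reproduces every
artifact byte-for-byte (verified by a rerun-diff test). Artifacts are plain
CSV/JSON with checksums recorded in `report.json`; an empty post-selection
feature set skips downstream stages with an explicit reason. The BRF stage
treats all retained attributes as continuous, matching how the ensemble was
applied in the original analysis.

## Problem sizes used in the test suite

Synthetic checks run at the study's own scale where that is cheap (283–566
patients) and at reduced ensemble sizes (5–11 voters, 15–50 trees) chosen
so the statistical properties under test (recall advantage, rank recovery,
m-stability) are already unambiguous; parameter-recovery runs use 10⁵
patients. The acceptance script runs the full default pipeline (283
patients, 9 × 7 benchmark, 21 voters × 100 trees).

## Known limitations

- Independence-given-class is the strongest simplification; effect
  directions and magnitudes match the published marginals but joint
  structure does not exist. An explicit correlation hook was considered and
  deferred (nothing published to calibrate it against).
- The published Relief-F weight scale and the published MDA/MDG scores are
  not recomputable from summary statistics; they are fixtures for the
  selection/consensus logic, not recomputation targets.
- C5.0 and boosted C5.0 are approximated by scikit-learn stand-ins and
  labelled as such.
- Binary outcomes only; the sign-vote ensemble has no multiclass extension.
- No missing-data handling: the source population table is complete and no
  imputation procedure is described.
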