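# pheoihd

Predicting **intraoperative hemodynamic instability (IHD)** during
pheochromocytoma surgery from routine preoperative variables.
Pheochromocytoma resection can release catecholamines into circulation and
destabilize blood pressure mid-surgery; knowing which patients are at risk
(and which clinical variables carry that risk) guides preoperative
preparation. This package is for biostatisticians and clinical data miners
who want the full analysis pipeline — from cohort to ranked risk factors —
as a tested, scriptable library.

The pipeline:

1. **Synthetic cohorts** — the original 283-patient dataset is not public,
   so a generator reproduces its published class-conditional statistics
   (18 mixed-type predictors, 26.1% event prevalence) for end-to-end runs.
2. **Relief-F** feature weighting: each attribute A is scored by contrasting
   k nearest hits H and misses M around sampled patients R,

   W(A) ← W(A) − Σⱼ diff(A, R, Hⱼ)/(m·k) + Σ_{C≠cls(R)} P(C)/(1−P(cls R)) · Σⱼ diff(A, R, Mⱼ)/(m·k),

   followed by threshold retention (the published −24 cutoff keeps 10 of 18
   features).
3. **Benchmark** of seven classifiers under nine validation schemes
   (hold-out 80/70/60%, 5/10/15-fold CV, bootstrap subsets of 50/100/200).
4. **Balanced random forest** for the 1:2.82 class imbalance: m forests,
   each trained on a per-class bootstrap of n rows, voting by sign,
   BRF(x) = sgn Σᵢ RFᵢ(x), with ties resolved toward the minority (IHD)
   class.
5. **Assessment** with the study's conventions (positive class = patients
   *without* IHD), accuracy/TPR/TNR/PPV/FPR/f1, ROC/AUC (trapezoid ≡
   Mann–Whitney), and percentile-bootstrap intervals.
6. **Consensus risk factors**: top-5 lists by MDA, MDG and Relief-F; features
   in ≥ 2 of 3 lists are the final predictors.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
>>> from pheoihd import ConfusionMatrix, metric_set
>>> metric_set(ConfusionMatrix(tp=85, fp=2, fn=15, tn=12)).as_dict()
{'accuracy': 0.8509, 'tpr': 0.85, 'tnr': 0.8571, 'ppv': 0.977, 'fpr': 0.1429, 'f1': 0.9091}
```

That is the published 114-patient holdout confusion matrix of the best
model: 85 of 100 event-free patients and 12 of 14 IHD patients recognized,
accuracy 0.8509. Note tpr (sensitivity) describes the *event-free* class —
the study's y = 0 = positive convention.

```python
>>> from pheoihd.importance import load_reference_importance, consensus_select, ConsensusConfig
>>> ref = load_reference_importance().set_index("feature")
>>> consensus_select(ref["mda"], ref["mdg"], ref["relief"], ConsensusConfig(k=5, min_lists=2))
['bmi', 'ctvalue', 'size', 'prevma', 'age']
```

The five consensus risk factors: body-mass index, enhanced-CT difference,
tumor size, the 24-h urine vanillylmandelic-acid ratio, and age — BMI and
CT difference lead because they appear in all three top-5 rankings.

A full synthetic run from the shell:

```sh
pheoihd run --out run1 --seed 11
```

writes `relief_weights.csv`, `benchmark.csv`, `brf_metrics.json`,
`brf_roc.csv`, `importance.csv` and `consensus.txt` into `run1/`, all
reproducible byte-for-byte from the seed. Individual stages are available
as `pheoihd simulate | relieff | benchmark | brf train | brf predict |
importance`.

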