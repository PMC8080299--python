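# actibout

Bout-level physical-activity phenotyping from epoch-labelled wrist-accelerometer
traces, with EHR-based control stratification and a cross-validated
type-2-diabetes (T2D) classification grid.

## The problem

Free-living wrist-accelerometer traces can be summarised far more richly than
"minutes of moderate activity per day". After an epoch classifier has labelled
every 30-second epoch with one of five behaviours — `sedentary`, `moderate`,
`walking`, `sleep`, `light_tasks` — the *structure* of activity (how long
sedentary spells last, how often walking bouts occur, how fragmented sleep is)
carries signal about metabolic health even when the aggregate 24-h activity mix
of cases and controls is nearly identical. This package implements that idea
end-to-end for researchers working with epoch-labelled actigraphy and linked
primary-care records:

1. **Bout features.** An activity *bout* is a maximal run of consecutive
   epochs with one label. For each participant a personalised night-sleep
   window is detected (the largest nearly-continuous block of sleep bouts per
   noon-to-noon day, averaged circularly across days), the remaining wake span
   is split into three equal phases (morning / afternoon / evening), and for
   every (activity a, phase p) cell three statistics are computed per day and
   averaged over wear days:

   - n(a, p) — number of bouts,
   - pct(a, p) — percentage of non-missing phase time spent in a,
   - len(a, p) — mean bout length in epochs,

   giving the 5 × 4 × 3 = **60-feature** representation. Per day and phase,
   Σₐ n(a,p)·len(a,p) equals the non-missing phase epochs exactly.

2. **Cohort construction from EHR.** T2D-positives are identified from
   self-report at assessment plus incident diabetes codes dated between
   assessment and device wear (insulin-in-first-year with age-at-diagnosis
   < 35 excluded as probable type 1 / monogenic). Controls are scored for
   physical-activity impairment: each coded condition class maps to a severity
   in {0, 1, 2} and the score is the mean severity of events in
   [wear_start − 6 months, wear_end + 1 month). Score < 0.5 → **Norm-0**
   (clean controls), ≥ 1.5 → **Norm-2** (highly impaired), in between →
   excluded. Training set **TS1** = T2D vs a half-sample of Norm-0; **TS2** =
   T2D vs Norm-2.

3. **Classification grid.** 3 algorithms (random forest, logistic regression,
   gradient boosting) × 3 feature sets (activity bouts only / 13
   sociodemographic-lifestyle variables only / combined) × 2 training sets =
   **18 models**, each evaluated by stratified 10-fold cross-validated AUC
   (mean ± 1.96·SE over folds) alongside an 80:20 stratified holdout, with
   per-class precision / recall / F1 and ROC curves. Missing demographic cells
   are filled by k-nearest-neighbour imputation (k = 5).

Because real cohorts of this kind are access-controlled, the package ships a
first-class **synthetic-data module**: a seeded generator producing epoch
traces (nocturnal sleep block + semi-Markov wake filling with shifted
negative-binomial bout lengths, calibrated so controls spend ≈ 5% moderate,
42% sedentary, 38% asleep, 5% light tasks, 10% walking over 24 h),
demographics with group shifts and MCAR missingness, and an EHR event stream
consistent with the group labels. Everything downstream is testable without
any data download.

## Worked example

```python
from actibout import bouts, cohort, models, synth

cfg = synth.PopulationConfig(n_t2d=150, n_control=300, n_impaired_control=150,
                             days=7, seed=11)
pop = synth.generate_population(cfg)

feats, phases, qc = bouts.features_table(pop.traces)      # 600 x 60
asn = cohort.build_cohort(pop.selfreport, pop.ehr, pop.wear)
ts1, ts2 = cohort.build_training_sets(asn, seed=11)       # ~150 vs 150 each
demo = models.impute_knn(pop.demographics)
results = models.run_grid((ts1, ts2), feats, demo, folds=10, seed=11)
print(models.auc_pivot(results).round(3))
```

which prints (about 40 s on one CPU):

```
feature_set         activity_only        combined        socio_only
training_set                  TS1    TS2      TS1    TS2        TS1    TS2
algorithm
gradient_boosting           0.757  0.551    0.808  0.639      0.708  0.580
logistic_regression         0.826  0.600    0.869  0.638      0.772  0.629
random_forest               0.780  0.600    0.824  0.631      0.739  0.609
```

Read it as: bout features alone discriminate cases from clean controls well
(TS1, AUC 0.76–0.83); combining them with sociodemographic variables always
helps (combined ≥ either set alone, per algorithm); and replacing clean
controls with highly impaired ones (TS2) degrades every model — impairment
from other conditions masks the T2D activity signature.

The same run from a shell:

```bash
actibout run-all --seed 11 --out runs/demo
```

writes `features.csv`, `cohort.csv`, `results_auc.csv`, `results_f1.csv`,
per-model ROC curves, sleep-distribution histograms and a `manifest.json`
that reproduces the run byte-for-byte.

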