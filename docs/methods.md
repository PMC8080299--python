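# Methods

This note records the models, numerical conventions and open design choices
behind `actibout`, in enough detail that a maintainer can predict the
package's behaviour on degenerate input and understand what the synthetic
experiments do and do not demonstrate.

## Epoch model and the bout hierarchy

Traces are sequences of 30-second epochs labelled from a six-symbol alphabet:
the five behaviours (`sedentary`, `moderate`, `walking`, `sleep`,
`light_tasks`) plus `missing`. The activity classes carry the standard MET
(metabolic equivalent of task) constants — sedentary 1.5, moderate 4.9,
walking 3.2, sleep 1.0, light tasks 2.2 — stored for reference; no
energy-expenditure summaries are derived from them.

A *bout* is a maximal run of one label. `missing` runs terminate bouts and
are excluded from all statistics. Bout extraction is run-length encoding;
the test suite checks it against an independently coded brute-force encoder
on random sequences.

**Analysis day.** All per-day computations use noon-to-noon days, so a
nocturnal sleep block is never split at midnight. Partial leading/trailing
days are dropped. Timestamps are ISO-8601, epoch indices 0-based, and all
intervals half-open `[start, end)`.

**Sleep window.** Per day, sleep bouts separated by non-sleep gaps of at
most `gap_tolerance_epochs` (default 60 epochs = 30 min; the notion of
"nearly continuous" sleep needs a concrete tolerance and this one is
conventional for actigraphy, and configurable) are merged; the merged block
containing the most sleep epochs is the day's window, ties broken by
earliest onset. Ranking by sleep content rather than span avoids rewarding
blocks padded with long gaps. The participant-level window is the circular
(unit-vector) mean of daily onsets and offsets — plain averaging would fail
for onsets straddling midnight. Days with no sleep epochs are flagged and
excluded; a participant with no usable day raises `SleepWindowError`.

**Phases.** The wake span (offset → next onset, circular) is divided into
three *equal* phases, morning / afternoon / evening; the sleep window is the
fourth phase. The four phases tile 1440 minutes exactly (property-tested).

**Feature matrix.** Bouts are split at phase boundaries and each fragment
counts as a bout of its own phase. This keeps the conservation identity —
per day and phase, Σ over activities of (bout count × mean bout length) =
non-missing phase epochs — exact, at the price of slightly inflating counts
for boundary-crossing bouts; assigning whole bouts to one phase would break
the identity. Percentages are phase-relative with non-missing epochs as
denominator; a phase whose epochs are all missing yields NaN percentages for
that day and is skipped by the across-day mean. Cells with zero bouts report
(0, 0, 0) — encoding mean length as 0 rather than NaN spares downstream
models a second imputation pass. The 7-day average is an element-wise
arithmetic mean over valid days; output order is activity-major with names
`<activity>_<phase>_<stat>`, 60 entries always.

Mean bout length is stored as a double; reconstructing activity epochs as
count × mean can differ from the integer total in the last ulp, so exactness
tests assert the rounded sum.

**24-h aggregation.** The phase-relative percentages are aggregated back to
24-h occupancy by weighting each phase percentage with its duration. This
aggregate is what the distribution report and the acceptance quantities use.

**Wear-time QC.** "Adequate wear" is ≥ 72 h of non-missing epochs
(boundary inclusive) and at least one day with ≥ 12 h observed in each half
of the wear period; both thresholds configurable. The 72-h rule mirrors
common accelerometry practice; there is no canonical definition.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes; it is
first-class, tested code, not a fixture.

**Per-day construction.** Each noon-to-noon day gets one sleep block with
onset ~ N(23:00, 30 min) and duration ~ N(gross, 45 min) (night-to-night,
within person), clamped inside the day; Poisson-many brief wake
interruptions (mean length 2 epochs) fragment the block. Wake time is filled
by a semi-Markov renewal process: pick an activity with phase-specific
probability, draw a bout length from a shifted negative binomial
(L = 1 + NB(r, p), minimum one epoch, mean m, dispersion r = 1.5), repeat.
Epoch-level missingness is completely at random (default 2%); demographic
cell missingness likewise (default 5%). MCAR is the simplest defensible
choice; no mechanism is implied by the problem.

**Calibration.** The long-run time share of activity a in a renewal process
is wₐE[Lₐ]/Σ w_bE[L_b], so picking weights wₐ ∝ shareₐ/E[Lₐ] reproduce any
target mix for any bout-length means. The default control profile targets
the canonical control mix (sedentary 42%, moderate 5%, walking 10%, light
tasks 5%, sleep 38% of the 24-h day): net sleep 0.38 × 1440 = 547.2 min,
with the expected interruption loss added back to the gross block duration.
Simulation recovers the sedentary and sleep shares within a fraction of a
percentage point at n = 200 (Monte-Carlo SE ≈ 0.12 pp).

**Between-person heterogeneity.** Every participant draws a personal profile
around the group profile: mean-one log-normal multipliers on bout-length
means (log-SD 0.35), occupancy shares (0.25, renormalised) and fragmentation
rate (0.5), and Gaussian shifts on habitual sleep onset (SD 35 min) and
duration (SD 50 min). Without this, all group members share one profile and
7-day averages separate groups almost perfectly — free-living populations
are not like that. Setting all scales to zero recovers the degenerate
single-profile population used in unit tests.

**Group effects.** The T2D profile lengthens sedentary bouts at constant
occupancy (×1.3 on the mean minus one), down-weights walking occupancy
(×0.8) and doubles sleep fragmentation, leaving the aggregate 24-h mix
nearly unchanged — the signal lives in bout structure, which is the premise
of the representation. Demographic shifts (older, higher body fat and waist,
more TV, less self-reported activity) give the sociodemographic channel
comparable discrimination. Impaired controls get effects pointing the *same
way* as the T2D effects (sedentary bouts ×1.25, walking ×0.72, fragmentation
×1.7, +2 pp sedentary share) so that stratum overlaps the case group: this
is what makes TS2 a noisy training set. Effect sizes were fixed once so that
the default population yields discrimination in the range typical for
free-living actigraphy case/control studies (TS1 combined AUC ≈ 0.81–0.87)
rather than trivial separability.

**EHR stream.** Non-impaired participants receive Poisson-many severity-0
events inside the scoring window plus arbitrary out-of-window history;
impaired controls receive 1 + Poisson(2) severity-2 events in-window and
their benign history only out-of-window, so their in-window mean severity is
exactly 2 and, with noise-free class labels, the cohort stage recovers the
strata perfectly (impaired → Norm-2, clean → Norm-0). A configurable
fraction (default 0.3) of T2D cases carry an incident diabetes code dated
between assessment and wear start instead of a self-report.

**Determinism.** One master seed spawns per-participant and per-table
substreams (`numpy` `SeedSequence.spawn`), so populations are byte-identical
for a given config regardless of generation order.

**What the synthetic experiments show — and do not.** Passing tests show the
*pipeline* is correct and that the analysis recovers structure the generator
injects (and finds none when it is absent). They say nothing about effect
sizes in real cohorts: the generator has no seasonality, no day-of-week
structure, no device non-wear clustered in time, no classifier label noise,
and its condition severity classes are a synthetic stand-in for licensed
clinical vocabularies.

## Cohort construction

Severity scale {0, 1, 2} with band thresholds 0.5 / 1.5 (configurable): the
scale granularity is a stand-in for a full per-code severity catalogue,
which is licensing-restricted. The scoring window is
[wear_start − 6 months, wear_end + 1 month); the trailing month absorbs
recording delay. The incident-diabetes window (assessment, wear_start) is
open at both ends. T2D-positives with high impairment scores are retained in
both training sets — excluding them would bias the case phenotype toward
uncomplicated disease. Norm-1 participants (intermediate impairment) enter
neither training set. The Norm-0 half-sample uses floor rounding on a
dedicated seeded stream, and the sample size is exposed as a parameter
rather than hard-coded at one half. Participants without EHR coverage can be
excluded as band-unknown via the `coverage` argument; by default all
participants are treated as covered, since the generator links everyone.

## Classification grid

Hyperparameters are library defaults with fixed seeds. Logistic regression
is fitted on z-scored features with the scaler fitted inside each training
fold (tree ensembles consume raw features); kNN imputation standardises
columns on observed statistics. Imputation is performed once on the full
demographics table before cross-validation — the imputer sees no outcome
labels, and per-fold re-imputation was judged not worth the complexity for
a missingness-completely-at-random table. The headline metric is the
10-fold CV mean AUC with a normal-approximation 95% CI (mean ± 1.96·SE over
folds); the 80:20 stratified holdout is computed alongside and labelled
`holdout` in outputs, because both protocols are in common use and they
answer slightly different questions. F1 is per class; the suite asserts it
equals the harmonic mean of the reported precision and recall to 1e-12.

**Null behaviour.** On populations with all effects switched off, CV mean
AUC scatters around 0.5 with a small *pessimistic* bias: training and test
folds are drawn without replacement from one finite sample, so chance
associations fitted in training folds reverse slightly in the complement.
Across null runs the grid's mean AUC sits at 0.48–0.51 and never
systematically above 0.5 — the signature of an unbiased, leakage-free
pipeline. A consequence is that a joint "all 18 models within 3 fold-SEs of
0.5" check is conservative-to-fragile: with 18 simultaneous t-like
statistics, occasional 3-SE excursions (always downward) occur even for a
perfect null generator. The shipped null-recovery test uses one fixed seed
declared in advance.

## Problem sizes

Default test and acceptance runs use populations of 90–600 participants and
4–7 wear days — large enough that Monte-Carlo error is small against the
stated tolerances (occupancy SE ≈ 0.12 pp at n = 200; AUC fold-SE ≈ 0.02–0.06
at n ≈ 300 per training set), and chosen as the problem sizes a desk-scale
replication of this design would use.

## Known limitations

- Sleep-window detection assumes one dominant nocturnal sleep block; shift
  workers and polyphasic sleepers would need a different anchor than
  noon-to-noon days.
- Phase-relative percentages are reported; the 24-h aggregate is derivable
  (and provided), but the two are not interchangeable when phase durations
  differ across participants.
- The generator's wake phases share one occupancy mix by default; diurnal
  gradients (e.g. evening sedentariness) are expressible but not defaulted.
- No Read-v2 ↔ CTV3 terminology mapping; condition classes are symbolic.
- No hyperparameter search or calibration analysis; raw feature importances
  are available from the fitted models but not interpreted.
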