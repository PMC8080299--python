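# Pipeline configuration schema for `actibout run-all --config <file>`.
# Every key is optional; omitted keys take the defaults shown here.

population:
  n_t2d: 100                # participants per group
  n_control: 100
  n_impaired_control: 50
  days: 7                   # wear days per participant
  seed: 0                   # master seed; spawns all substreams
  # case effects on the activity profile
  sedentary_bout_len_mult: 1.3
  walking_rate_mult: 0.8
  sleep_frag_mult: 2.0
  # impaired-control effects (same direction as the case effects)
  impaired_sedentary_bout_len_mult: 1.25
  impaired_sedentary_share_shift: 0.02
  impaired_walking_rate_mult: 0.72
  impaired_sleep_frag_mult: 1.7
  demo_missing_rate: 0.05   # MCAR cell missingness in demographics
  epoch_missing_rate: 0.02  # MCAR epoch missingness in traces
  benign_event_rate: 1.0    # expected in-window severity-0 events
  out_window_event_rate: 1.0
  impaired_event_rate: 2.0  # extra in-window severity-2 events (plus one)
  incident_t2d_frac: 0.3    # cases identified via incident EHR code

gap_tolerance_epochs: 60    # sleep-merge tolerance (30 min)
qc_min_hours: 72.0          # adequate-wear threshold
window_before_months: 6     # severity-scoring window before wear start
window_after_months: 1      # ... and after wear end
band_thresholds: [0.5, 1.5] # Norm-0 / Norm-1 / Norm-2 cut points
impute_k: 5                 # kNN imputation neighbours
folds: 10                   # stratified CV folds
train_fraction: 0.8         # holdout split
holdout: true               # also run the 80:20 evaluation
seed: 0                     # sampling / CV seed
histogram_bins: 30
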