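seed: 0
grid:
  x_min: 0.0
  y_min: 0.0
  cell_side: 3.03315017762062
  n_cols: 60
  n_rows: 60
species:
- name: seal_like
  response: seal_like
  n_presences: 300
  uses_haulouts: true
- name: porpoise_like
  response: porpoise_like
  n_presences: 300
  uses_haulouts: false
scenarios:
- label: current
  mean_slr_m: 0.0
  sst_delta: 0.0
  sss_delta: 0.0
  current_delta: 0.0
- label: RCP6.0
  mean_slr_m: 0.39
  sst_delta: 1.35
  sss_delta: 1.0
  current_delta: 0.0
- label: RCP8.5
  mean_slr_m: 0.65
  sst_delta: 2.7
  sss_delta: 2.0
  current_delta: 0.0
n_background: 10000
n_haulouts: 25
bias_bandwidth_km: 40.0
rm_grid:
- 0.5
- 1.0
- 1.5
- 2.0
- 2.5
- 3.0
- 3.5
- 4.0
- 4.5
- 5.0
feature_classes:
- L
- Q
- LQ
k_folds: 5
fit_tol: 1.0e-06
fit_max_iter: 5000
overlap_threshold: kappa
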