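exposure: exposure.tsv
outcome: outcome.tsv
ld_matrix: ld.tsv
out_dir: out
outcome_name: depression
seed: 20220830
clump:
  p_threshold: 5.0e-8
  window_kb: 10000
  r2_threshold: 0.001
palindromic:
  policy: infer_by_eaf
  eaf_window: 0.08
estimators:
  n_boot: 500
  phi: 1.0
presso:
  n_sim: 1000
  outlier_alpha: 0.05
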