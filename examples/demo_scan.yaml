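# Demo: simulate three populations with an implanted sweep, then scan.
# Run:  tbscan scan --config examples/demo_scan.yaml --out demo_out
seed: 7
out_dir: demo_out
simulation:
  pop_labels: [upland_jap, irrigated_jap, indica]
  n_diploids_per_pop: [40, 40, 40]
  drift_F_per_pop: [0.15, 0.15, 0.3]
  chrom_length_bp: 1000000
  n_sites: 10000
  sweep:
    focal_position_bp: 500000
    target_pop: upland_jap
    intensity_w0: 0.8
    decay_length_bp: 20000
    high_freq_floor: 0.9
thresholds:
  window_quantile: 0.005
  pbs_quantile: 0.05
  hka_alpha: 0.05
  fixation_fst_cutoff: 0.9
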