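# Demo pipeline configuration: a simulated breed with one planted
# differentiated window, scanned with the default thresholds.
seed: 7
out_dir: runs/demo

simulate:
  n_samples_per_group: 40
  n_snps: 2000
  n_chromosomes: 4
  spacing_bp: 25000
  background_c: 0.01
  missing_rate: 0.01
  breed: SIM
  planted_windows:
    - {chrom: 2, start_snp: 200, n_snps: 15, delta: 0.4}

qc:
  max_missing_rate: 0.02
  hwe_alpha: 1.0e-7
  rel_cutoff: 0.75
  ld_window_snps: 50
  ld_step_snps: 5
  ld_r2_max: 0.2

structure:
  k: 10

scan:
  estimator: weir_cockerham
  smooth_window_snps: 9
  smooth_kernel: uniform_mean
  outlier_quantile: 0.99
  region_merge_gap_bp: 1000000
  clamp_negative: true
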