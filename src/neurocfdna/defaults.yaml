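# Default pipeline configuration: the published analysis thresholds and the
# study-shaped simulated cohort. Any field may be overridden in a user config.
mode: simulate_and_run
seed: 0
output_dir: neurocfdna_out

thresholds:
  p_threshold: 1.0e-05     # sliding-window DMR significance
  min_abs_delta: 0.6       # |neuron - plasma| beta refinement
  window_probe_count: 5
  min_mean_quality: 9      # reads below mean Phred 9 fail
  min_length: 200          # reads shorter than 200 bp are excluded
  max_primer_edits: 2
  min_span_fraction: 0.95  # full-molecule span requirement
  conversion_failure_tolerance: 0
  cutoff: 0.05             # neuron-derived ratio diagnostic cutoff (>5%)
  min_reads: 100

cohort: study_shaped       # 25 aged controls, 13 AD, 6+6 MCI, 10 young, x2 aliquots

reads:
  n_reads: 2000
  blood_cpg_meth_prob: 0.95
  neuron_cpg_meth_prob: 0.0
  conversion_failure_prob: 0.0
  subst_error_rate: 0.005
  mean_quality: 12.0
  quality_sd: 3.0
  truncated_read_prob: 0.1
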