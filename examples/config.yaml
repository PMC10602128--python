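# Example run configuration. Omitted keys take package defaults.
seed: 5

simulation:
  n: 1000
  positive_fraction: 0.19
  baseline_mean: 1.05
  baseline_sd: 0.08
  severity_sd: 0.25

meta_roi:
  temporal_cutoff: 1.23
  mtl_cutoff: 1.30
  neo_cutoff: 1.73

classifier:
  test_fraction: 0.20
  k: 5
  repeats: 2
  threshold: 0.5

attribution:
  method: sampled       # or "exact" for panels with <= 15 regions
  n_background: 100
  n_permutations: 200

theta:
  lower_percentile: 1
  upper_percentile: 99
  percentile_scope: per_scan   # or cohort_per_region
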