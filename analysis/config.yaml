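# Shared configuration for the numbered analysis drivers.
# Thresholds are the standard screens; the synthetic cohort mirrors the
# study conditions (family pairs, ~2 weeks of nights, three devices, diary).
out_dir: results/cohort_run
seed: 20240915
simulate:
  n_families: 50
  nights_min: 10
  nights_max: 16
agreement_n_iter: 5000
write_hypnograms: false
make_figures: true
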