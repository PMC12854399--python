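# Demo pipeline configuration: full-size synthetic cohort, default tariffs.
out_dir: glycea_out
seed: 42
psa_n_sims: 10000
psa_uncertainty_scale: sd
iptw_covariates: [age, bmi]
cohort_spec: {}   # empty -> the default study-structure cohort (128 / 73)
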