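# Quick demonstration config: small permutation/null counts for a fast run.
# For an analysis-scale run use b_perms: 1000 and n_null: 20 (the defaults
# in examples/config_study.yaml).
synthetic:
  seed: 42
b_perms: 100
n_null: 5
d_max: 0.5
seed: 42
outdir: scovnet_out
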