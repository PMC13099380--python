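# Study-scale analysis constants: 2% density steps from D_min to 0.5,
# 1000 label permutations, 20 HQS null networks, omnibus gate p <= 0.02.
# Point cohort_path/atlas_path at real data to analyze it instead of a
# synthetic cohort.
synthetic:
  seed: 7
step: 0.02
d_max: 0.5
b_perms: 1000
n_null: 20
gate_alpha: 0.02
dunn_alpha: 0.05
fdr_alpha: 0.05
seed: 7
outdir: scovnet_out
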