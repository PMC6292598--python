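# Full-scale evaluation grid: 36 scenarios x 9 formulations x 2 covariance
# structures at 1000 replicates. Not a desk-scale run.
n_clusters = 12
subjects_per_cluster = 20
scenarios = all
formulations = all
structures = all
n_reps = 1000
master_seed = 20181206
out_dir = results/full
ci_reference = normal
mse_mode = conditional
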