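# Desk-scale subset: the directional core of the coverage comparison
# (exposure-time scenarios punish calendar-only formulations) at 200
# replicates under the CS working covariance.
n_clusters = 12
subjects_per_cluster = 20
scenarios = D1, D9, D17, D27
formulations = M4, M7, M8, M9
structures = CS
n_reps = 200
master_seed = 20181206
out_dir = results/desk
ci_reference = normal
mse_mode = conditional
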