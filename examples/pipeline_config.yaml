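seed: 1
min_asp: 2
min_glu: 2
grid_lo: 2.0
grid_hi: 16.0
grid_width: 0.01
wl_log_f0: 1.0
wl_log_f_min: 1.0e-05
wl_flatness: 0.8
wl_check_every: 200000
wl_max_steps: 600000000
muca_steps: 400000000
muca_chains: 4
muca_thinning: 100
muca_max_records: 400000
muca_ref_steps: 100000000
muca_ref_thinning: 2000
block_samples: 10000000
ga_runs: 1000
ga_population: 100
ga_mutation_rate: 0.1
ga_generations: 500
slice_delta: 0.1
k_max: 8
kmeans_restarts: 50
ga_bin_width: 0.1
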