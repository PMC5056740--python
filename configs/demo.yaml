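# Demonstration pipeline: 50 designed environments, 11-variety panel.
# Thresholds default to the published classification values; override here
# to explore alternatives.
outdir: results/demo
n_environments: 50
seed: 1
yield_ratio: 0.75
severity_bounds: [0.25, 0.50]
timing_factor: 0.90
n_rank_groups: 5
linkage_method: ward
sensitivity_sizes: [1, 3, 5, 7, 9, 11]
sensitivity_replicates: 50
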