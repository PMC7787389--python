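# four spatially separated surname groups with strong endogamy
n_persons: 20000
n_groups: 4
surnames_per_group: 50
zipf_exponent: 0.8
endogamy: 0.95
grid_extent: [0.0, 1.0, 0.0, 1.0]
group_centers: [[0.2, 0.2], [0.8, 0.2], [0.2, 0.8], [0.8, 0.8]]
group_spread: 0.12
block_size: 0.05
ses_group_means: [20.0, 45.0, 70.0, 95.0]
ses_noise_sd: 2.0
seed: 7
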