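grid_edge: 25
excitatory_kernel: 19
inhibitory_kernel: 5
within_density: 0.35
within_sigma: 5.0
between_density: 0.08
between_sigma: 3.0
w_init_max_within: 0.01
w_init_max_between: 0.45
w_max: 1.0
tau_e: 2.5
tau_i: 5.0
tau_adapt: 15.0
adapt_strength: 4.0
output_threshold: 0.1
k_local: 0.6
k_global: 0.07
tau_global: 8.0
ltp: 0.004
ltd: 0.0002
ltd_hetero: 0.0006
pre_threshold: 0.15
post_threshold: 0.15
noise_baseline: 0.3
noise_input: 2.0
stim_amplitude: 6.0
train_stim_steps: 16
isi_threshold: 18.0
isi_max_steps: 1000
test_stim_steps: 2
test_record_steps: 30
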