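# Scaled-down demonstration arm: small trees, 20 replicates per generating
# mode, all five sampling-fraction levels, random trimming.
# Runs in a few hours on one CPU.
size_class: small
extinction_level: low
generating_modes: [ETD, CTD, CR]
n_replicates: 20
sf_levels: [1.0, 0.8, 0.6, 0.4, 0.2]
regime: random
seed: 20240101
models_to_fit: [CR, CTD, ETD]
optimizer_method: lbfgs
max_cycles: 3
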