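# Minimal smoke-test configuration (minutes on one CPU): tiny custom trees
# standing in for the small size class.
size_class: small
extinction_level: low
generating_modes: [ETD, CTD, CR]
n_replicates: 2
sf_levels: [1.0, 0.6]
regime: random
seed: 7
crown_age: 6.0
band: [10, 40]
max_cycles: 2
optimizer_method: lbfgs
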