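# Full-replication arm (cluster scale): medium trees, low extinction,
# taxonomically biased trimming (one or two heavily trimmed sub-clades).
size_class: medium
extinction_level: low
generating_modes: [ETD, CTD, CR]
n_replicates: 100
sf_levels: [0.8, 0.6, 0.4, 0.2]
regime: biased
misspec_map:
  0.8: [1.0, 0.6]
  0.6: [1.0, 0.8, 0.4]
  0.4: [1.0, 0.8]
seed: 20240103
models_to_fit: [CR, CTD, ETD]
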