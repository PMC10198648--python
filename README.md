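# hiddensse

Evaluation of hidden-state SSE (state-dependent speciation–extinction)
model selection and parameter estimation under incomplete and
taxonomically biased taxon sampling.

The package simulates ultrametric phylogenies with a jointly evolving
*examined* trait (observed at the tips) and a *concealed* trait (never
observed), degrades them to target sampling fractions, fits competing SSE
parameterizations by maximum likelihood with per-state sampling-fraction
corrections, and quantifies model-selection error rates (false
positives/negatives by AICc) and rate-estimate accuracy — including the
effects of mis-specifying the sampling fraction.  A reduced Bayesian arm
places a uniform prior on the sampling fraction and compares
trait-dependent vs trait-independent models by stepping-stone marginal
likelihoods.

## Layout

| module | role |
| --- | --- |
| `hiddensse.states` | combined examined × concealed state spaces, rate sets, generating modes (ETD / CTD / CR) |
| `hiddensse.simulate` | exact continuous-time (Gillespie) clade simulation with trait evolution; rejection sampling into tip-count bands |
| `hiddensse.trim` | random and taxonomically biased tip removal, state-proportion and lost-transition diagnostics |
| `hiddensse.likelihood` | hidden-state SSE pruning likelihood (numba-jitted adaptive Dormand–Prince integrator), per-state sampling fractions |
| `hiddensse.fit` | maximum-likelihood fitting (ETD/CTD/CR/ECTD), AICc, Akaike weights, model selection |
| `hiddensse.metrics` | false-positive/negative rates, parameter-accuracy summaries, Sackin imbalance |
| `hiddensse.experiment` | config-driven orchestration of study arms; resumable, byte-reproducible CSV outputs |
| `hiddensse.bayes` | 2×2-state Bayesian variant: MCMC with a sampling-fraction prior, stepping-stone marginal likelihoods, Bayes factors |

## CLI

```sh
# simulate 5 small ETD trees
hiddensse simulate --mode ETD --crown-age 13.4 --band 100,250 --n-trees 5 \
    --seed 1 --outdir out/sim

# trim one to 60% of its tips
hiddensse trim --tree out/sim/ETD_0000.nwk --states out/sim/ETD_0000.states.tsv \
    --target-sf 0.6 --seed 1 --out-prefix out/trimmed

# fit one model
hiddensse fit --tree out/trimmed.nwk --states out/trimmed.states.tsv \
    --model ETD --rho 0.6,0.6,0.6 --out out/fit.csv

# run a configured study arm, then summarize error rates
hiddensse experiment --config configs/tiny_ci.yaml --outdir out/exp
hiddensse summarize --selection out/exp/selection.csv
```

`configs/demo.yaml` is a scaled-down small-tree arm (hours);
`configs/*_full.yaml` are the full-replication arms (cluster scale).

## Notes

* Trees are exchanged as Newick (branch lengths in MY) plus tab-delimited
  tip-state tables (`tip  examined  concealed`); event logs as CSV.
* All randomness flows through explicit seeds; identical seeds give
  byte-identical outputs, and experiment runs resume from per-task caches.
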