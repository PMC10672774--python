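# lasim

A probit-binomial model of local-anesthetic effect scores: a seedable
forward simulator, a Bayesian hierarchical estimator, and Kaplan-Meier
duration analysis.

The model: a latent log-scale "concentration" decays linearly from 100 with
slope -1 (rescaled by `1 - adr` when adrenaline is present); the probability
of reacting to a needle stimulus at time `t` is the upper normal tail
`1 - Phi((C(t) - mu) / sigma)` with a drug/individual-specific transition
`(mu, sigma)`; the observed score out of 6 stimulations is binomial in that
probability.  Hierarchically, each animal's `mu` is normal around a per-drug
mean (variant 2 adds a shared per-animal offset `d`) and `sigma` is
lognormal.  The anesthetic effect is deemed subsided at the third
consecutive score of 6 (right-censored at the end of the grid otherwise).

## Layout

- `lasim.model_core` — deterministic core: concentration decay, reaction
  probability, half-effect time, score distribution.
- `lasim.simulator` — cohort simulation, triple-6 stopping rule, censoring.
- `lasim.inference` — both model variants fitted by a built-in NUTS sampler
  (`lasim._nuts`, analytic gradients in `lasim._kernels`), posterior
  summaries, rank-normalized split R-hat / bulk ESS diagnostics (via arviz),
  WAIC and PSIS-LOO, and the closed-form mu-reversal probability.
- `lasim.survival` — product-limit estimator with log-Greenwood 95% CIs and
  Brookmeyer-Crowley median CIs (matches R's `survival` defaults).
- `lasim.synthetic_data` — bundled published hyperparameter sets
  (`table1_model1`, `table1_model2`, `table5_param1`, `table5_param2`),
  study-shaped cohort generation, CSV I/O.
- `lasim.cli` — `simulate`, `fit`, `durations`, `recover` commands.

## CLI

```sh
# simulate a 100-animal cohort with the adjusted simulation parameters
lasim simulate --params table5_param2 --n 100 --seed 1 --out sim_out

# Kaplan-Meier medians per arm
lasim durations --durations sim sim_out/durations.csv --out km_out

# fit both model variants to a score table (reduced budget shown)
lasim fit --scores sim_out/scores.csv --chains 4 --iterations 2000 \
    --warmup 1000 --thin 1 --seed 1 --out fit_out

# parameter-recovery harness
lasim recover --params table1_model2 --n 51 --seed 1 --out recover_out
```

Score CSVs are long-format `animal_id, arm, time_min, score`; duration CSVs
are `animal_id, arm, time_min, event`.  Every output directory carries a
`run_metadata.json` with the seed and parameter provenance.

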