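# antforage

Stochastic feedback model of foraging regulation in harvester ant
(*Pogonomyrmex barbatus*) colonies, with the statistical pipeline needed to
fit and evaluate it on event traces of ants crossing a counting line.

Harvester ant colonies adjust how many foragers leave the nest, moment to
moment, without central control or spatial cues such as pheromone trails.
The mechanism is a feedback loop at the nest entrance: each forager
returning with a seed briefly contacts outgoing foragers queued in the
entrance tunnel and stimulates departures, so the outgoing rate tracks the
return rate — which itself tracks food availability. This package is for
behavioural ecologists and modellers who want to simulate that loop, test
whether a returning-forager stream is Poisson, calibrate the model's single
free parameter against observed traffic, and reproduce the removal-
experiment analyses on synthetic or field-derived data.

## The model

Time is divided into equal slots (1 s by default). With `A_n` returning
foragers arriving at the start of slot `n` and `D_n` foragers departing at
its end, the departure rate `α_n` evolves as

    α_n = max(α_{n−1} − q·D_{n−1} + c·A_n − d,  α)      α_0 = 0
    D_n ~ Poisson(α_n)

where `c` is the boost per returning forager (the one fitted parameter),
`q` the depletion per departure (each departing ant empties a place in the
entrance-tunnel queue), `d` a per-slot decay of responsiveness, and `α` a
floor reflecting the low baseline rate at which ants leave even when no
foragers return. Fixed values from field calibration: `q = 0.05`, `d = 0`,
`α = 0.01` ants/s. A simpler linear model (baseline rate plus a term
proportional to the returns in a recent window τ) is included for
comparison.

The package provides:

- `simulate_feedback` / `simulate_linear` — stochastic simulators, plus a
  deterministic expectation mode used as a test oracle;
- `PoissonIntervalFit` / `poisson_fit_report` — exponential interarrival
  fit (MLE), total-variation fit error, lag-1 independence check;
- `FeedbackCalibrator` / `sweep_c` — grid sweep of `c` scored by relative
  RMSE between simulated and observed outgoing rates, averaged over
  repeated stochastic runs (a scikit-learn style estimator; composes with
  sklearn model selection), with `replicate_rmse` and `heldout_colony_c`
  for variability analysis;
- `rect_smooth`, `trace_correlation`, `rate_trend_test`,
  `compare_correlations` — the smoothed-trace correlation analysis across
  trials;
- `gen_poisson_returns`, `gen_removal_trial`, `gen_paired_trial` —
  synthetic removal-experiment generators with known ground truth;
- an `antforage` CLI (`synth`, `simulate`, `fit`, `poisson-test`,
  `correlate`) over a simple CSV event-trace format.

## Worked example

```python
from antforage import (FeedbackParams, SyntheticTrialSpec, gen_paired_trial,
                       FeedbackCalibrator, poisson_fit_report, gen_poisson_returns)

# 1. Is a returning-forager stream Poisson?
rep = poisson_fit_report(gen_poisson_returns(0.8, (0, 2000), seed=1))
print(f"returns: rate {rep.rate:.3f}/s  tv_error {rep.tv_error:.3f}  "
      f"lag1 {rep.lag1_correlation:.3f}  (n={rep.n_intervals})")

# 2. Recover the stimulation parameter from a synthetic removal trial.
params = FeedbackParams(c=0.12)
trial = gen_paired_trial(SyntheticTrialSpec(return_rate=0.8,
                                            true_params=params, seed=42))
cal = FeedbackCalibrator(n_iterations=200, random_state=0)
cal.fit(trial.returning, trial.outgoing)
print(f"best c = {cal.best_c_:.2f}  (mean relative RMSE {cal.rmse_curve_.min():.3f})")
```

prints

```
returns: rate 0.795/s  tv_error 0.013  lag1 0.001  (n=1585)
best c = 0.12  (mean relative RMSE 0.102)
```

The fitted exponential rate matches the generating rate (0.8 ants/s) and the
tiny total-variation error and near-zero lag-1 correlation confirm the
Poisson structure; the sweep recovers the true `c = 0.12` exactly, and the
residual RMSE of ~0.10 is the level set by the model's own departure
randomness. The same workflow runs from the shell: `antforage synth` writes
a trace CSV, `antforage fit` sweeps `c` on it.

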