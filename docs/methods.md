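# Methods

## The feedback model

The colony's outgoing-forager rate is modelled as a discrete-time birth–
death-style recursion driven by the returning-forager stream. Slots are
`slot_duration` seconds long (default 1 s, so per-slot rates read directly
as ants/s); arrivals `A_n` are credited at the start of slot `n` and
departures `D_n` occur at its end, so slot `n`'s own arrivals raise its
departure rate while the previous slot's departures deplete it:

    α_n = max(α_{n−1} − q·D_{n−1} + c·A_n − d,  α_floor),   α_0 = 0
    D_n ~ Poisson(α_n)

Given the rates, departures are independent across slots and independent of
the arrivals. The floor applies from slot 1 onward (the `max` makes the
stated `α_0 = 0` and the invariant `α_n ≥ α_floor > 0` for `n ≥ 1`
compatible). The stationary behaviour is governed by the ratio `c/q`: mean
departures per slot settle near `(c/q)·Ā` for mean arrival rate `Ā`, which
is how `c` is identified from data.

Parameters, units and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `c` | departure-rate boost per returning forager | ants/slot per arrival | fitted (grid 0.01–0.25) |
| `q` | depletion per departure (entrance-queue emptying) | ants/slot per departure | 0.05 |
| `d` | per-slot decay of responsiveness | ants/slot | 0 |
| `α_floor` | baseline departure rate with no returns | ants/slot | 0.01 |
| `slot_duration` | slot length | s | 1 |

`q = 0.05`, `d = 0` and `α_floor = 0.01` ants/s are the field-calibrated
constants; only `c` is fitted. An *expectation mode* replaces the Poisson
draw by `D_n := α_n`; it is not part of the behavioural model but gives a
deterministic trajectory used as an independent oracle in tests and for
noise-free self-consistency checks.

The simpler linear model (`x(t) ~ Poisson(λ_b) + Poisson(λ_ac · f(t, τ))`,
with `f` the number of returns in the half-open window `(t−τ, t]`) is
retained for comparison. Rates are per second; the half-open window avoids
double counting at edges. Its weakness — a single integration window τ
cannot fit all foraging rates — is what motivates the per-contact feedback
model.

## Poisson diagnostic

Interarrival gaps are fitted with the exponential MLE (rate = reciprocal
mean; parameter-free and consistent with reporting the fitted rate's
reciprocal as a mean separation time). Goodness of fit is the total
variation distance between the empirical gap distribution and the fitted
exponential, both discretised to bins of `bin_width` (default one timestamp
unit — one frame for frame-resolved video at 30 fps), with an open-ended
tail bin absorbing the remaining exponential mass. Binned PDFs are
compared; a survival-curve comparison would be an alternative discretisation
and is not implemented. Independence is checked by the sample correlation
of successive gaps. The diagnostic window is configurable; the field
protocol used the pre-removal period 60–240 s. Note the TV statistic
shrinks with both sample size and rate: at a mean gap of ~30 bins its
large-sample floor is near 0.06, at ~5 bins near 0.02 — the fit is
intrinsically better at high foraging rates.

## Calibration of c

For each candidate `c` on the grid (default 0.01–0.25, step 0.01 — matching
the precision of the range endpoints), the observed returning series drives
`n_iterations` (default 200) stochastic simulations; each is compared with
the observed outgoing series by relative RMSE (RMSE of per-slot differences
divided by the observed mean, hence dimensionless); the per-candidate
scores are averaged and the argmin taken, ties broken toward the smallest
`c`. Iteration streams derive from the master seed through numpy
`SeedSequence` spawning (one child stream per candidate; iterations are
vectorised within a stream), so sweeps are bit-reproducible.

**Scoring compares rates, not raw counts.** The default scoring rect-
smooths both series (radius 25 slots) before the RMSE. Scoring raw per-slot
Poisson counts (`scoring="slots"`) is available but biased as an estimator
of `c`: the expected squared error decomposes into a squared rate mismatch
plus the simulated count variance, and the variance grows ≈ linearly in `c`
(per-slot variance ≈ `(c/q)·Ā`), shifting the argmin to roughly
`q/(2·Ā·slot_duration)` below the true value — 0.02–0.05 for field-
realistic rates, i.e. several grid steps. Smoothing suppresses the count-
variance term by the window size while leaving the rate mismatch intact, and
parameter-recovery experiments on synthetic trials then find the true `c`
to within one grid step. `scoring="segments"` (mean rates over the
pre/removal/post windows) achieves the same debiasing with a coarser
summary. The RMSE magnitudes reported by the sweep are therefore on the
smoothed-rate scale; raw-count RMSEs (as produced by `scoring="slots"` or
`replicate_rmse`) are larger, being dominated by per-slot Poisson noise.

Only `c` is fitted; `q`, `d`, `α_floor` stay fixed. No gradient-based
optimisation is used — the grid matches the reporting precision and the
objective is noisy.

Two variability procedures contextualise the fit:

- `replicate_rmse`: from one returning series, simulate replicate outgoing
  traces A, B, C per repeat and score A–B and A–C with A as reference.
  This is deliberately computed on raw counts — it measures how much
  disagreement the model's own departure randomness produces, which is the
  natural error floor for any count-level comparison. It is large at low
  return rates (departures hover near the floor; relative noise ~
  `1/√mean`) and small at high rates.
- `heldout_colony_c`: per colony, fit `c` on two designated trials,
  average, and score the remaining trial(s) at the averaged `c` (same
  scoring as the sweep). Colonies with fewer than three trials are skipped
  with a warning. Which two trials anchor the fit is caller-supplied or a
  seeded random draw — any fixed choice is as defensible as another.

## Trace analysis

Event traces are binned into half-open slots `[kΔ, (k+1)Δ)`. The travel-
time offset (camera-to-nest transit) is added to returning timestamps and
subtracted from outgoing ones; events shifted outside the trial span are
dropped with a logged count. The removal-trial windows default to
pre 0–240 s, removal 240–430 s, post 500–1100 s, with the 430–500 s gap
(time for ants past the camera to reach the nest) excluded from all segment
statistics; published accounts of this protocol occasionally give the
removal end as 420 s, and the windows are configurable. Smoothing is a
moving-average rect filter of radius 25 slots whose window truncates at the
series boundaries (no padding — no invented data at the edges; the interior
is an exact 51-slot mean). Per-trial correlations are Pearson coefficients
between the smoothed returning trace and a smoothed outgoing trace
(observed, or freshly simulated at the fitted `c`), over the full trial by
default. Across trials, the rate trend is a Spearman rank correlation
(midranks for ties) of the per-trial correlation against the trial-wide
mean return rate, with the normal approximation `z = ρ√(n−1)`; the
simulated-versus-observed comparison is a *paired* t-test (the same trials
appear in both columns; a two-sample variant is available). Constant inputs
make a correlation undefined and are reported as NaN with a warning; a
zero-variance paired difference is reported as degenerate rather than as a
finite t.

## Synthetic data

Generators emulate the statistical structure the analyses assume:

- homogeneous Poisson returning streams at 0.1–1.2 ants/s (the observed
  field range), built from i.i.d. exponential gaps;
- the removal design — returns suppressed during the removal window and the
  430–500 s gap, resuming instantaneously at the post-window start at the
  pre-removal rate (any lag in recovery belongs to the colony's outgoing
  response, which the model produces, not to the returning stream);
- paired trials whose outgoing series come from the feedback model itself
  under known parameters, with the true `c` recorded for recovery scoring.

An optional observation-noise model roughens the outgoing counts to emulate
imperfect observation of a real colony: each slot gains
`Poisson(m) − Poisson(m)` counts (mean zero, variance `2m`, default
`m = 0.5`, clipped at zero counts). It is a construction of this package —
real colonies differ from the model in unmodelled ways (nest architecture,
weather, count error), and this noise is a generic stand-in for all of
them, labelled `synthetic` in trial metadata. With it switched on, the
simulated outgoing trace correlates better with the returning trace than
the "observed" (noisy) one does, reproducing the direction of that
comparison; the *magnitude* of such test statistics on synthetic data says
nothing about any real colony.

What passing tests on these generators show: the pipeline is self-
consistent (the sweep recovers the generating `c`; the diagnostics detect
the Poisson structure they assume; directional contrasts between low and
high rates emerge from the model alone). What they do not show: that the
model describes real colonies — field traces have non-stationary rates,
travel-time jitter, correlated counting errors and day effects that the
generators deliberately omit.

## Numerical choices and problem sizes

- All stochastic components take explicit seeds; ensembles and sweeps
  derive sub-seeds from one master seed via `SeedSequence` spawning, and
  identical seeds give bit-identical outputs.
- Ties in the sweep argmin go to the smallest `c`; grid values are rounded
  to 10 decimals to keep `arange` artefacts out of reported optima.
- Degenerate inputs (empty traces, constant series, zero observed means,
  colonies with too few trials) raise or warn rather than returning
  misleading numbers.
- Standard problem sizes used throughout the tests and the acceptance
  script: 1,100-slot trials (the 0–1100 s design at 1-s slots), 200 sweep
  iterations, 20-trial recovery studies, 62-trial correlation ensembles,
  ~2,000-event diagnostic streams. These match the scale of the field
  design while keeping a full run to minutes on one CPU.

## Known limitations

- No spatial structure, pheromone trails, nest-architecture or weather
  effects; the model is a single scalar-rate feedback loop.
- The linear model is simulated but has no fitting routine (its window τ is
  the known obstacle, and it is retained only as a baseline).
- `q`, `d` and `α_floor` are fixed, not jointly fitted; colonies that
  genuinely differ in these constants will fold those differences into `c`.
- The TV diagnostic compares binned PDFs; heavy discretisation of very
  sparse streams (few intervals, fine bins) inflates the statistic.
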