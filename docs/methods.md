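# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `gluforecast`, and what the synthetic-data experiments do
and do not demonstrate.

## Problem setting

The input is a univariate CGM trace: timestamped blood-glucose readings in
mmol/L at roughly 15-minute intervals from a single wearer.  The task is
multi-step-ahead forecasting with the *direct* strategy: for each (lag,
horizon) pair a separate model maps a window of `lag` consecutive readings
to the single reading `horizon` steps past the window's end.  The canonical
scenario grid pairs windows of 3, 10, 13, 18, 20 and 30 samples with
horizons of 5, 15, 20, 25, 30 and 60 steps, labelled "5 min" … "60 min".
The labels are kept as report names only: at 15-minute sampling a literal
3-minute window contains no samples, so lags and horizons are defined as
counts of samples throughout.  (The recursive and MIMO multi-step
strategies are deliberately out of scope; direct models match the
per-horizon experiment structure.)

## Data handling

* **Windowing** treats the series as index-regular and ignores timestamp
  gaps by default, because no principled gap policy exists for a univariate
  trace; `to_supervised(..., max_gap=...)` optionally drops any sample whose
  window+target span crosses a gap larger than the threshold.
* **Split** is chronological, train = first `floor(0.75 n)` samples.  Floor
  is used because it is deterministic and errs toward more test data.
* **Scaling** is min–max to [0, 1], fitted on the pooled training windows
  and targets only.  Test values outside the training range map outside
  [0, 1] and are never clipped — clipping would hide distribution shift
  from the model.  Metrics are always computed after inverse scaling, in
  mmol/L: error values around 2–3 mmol/L in published CGM work are only
  interpretable in original units.
* **CSV dialect**: two columns `Time,BGL`, month/day/year timestamps
  without zero padding on a 24-hour clock.  Duplicate timestamps are an
  error rather than being averaged, since silent aggregation hides sensor
  faults.  Out-of-order rows are re-sorted with a counted warning.

## Architectures

All five models end in a single linear output unit (one scalar forecast per
window).  Design points that were genuinely open:

* **Recurrent activation is ReLU by default** (tanh available via
  `activation="tanh"`).  This matches the stated design of the hybrid
  recurrent stage; ReLU recurrent cells are unconventional but stable here
  because the pooled feature sequences are short (≤ 15 steps) and inputs
  are scaled to [0, 1].  The GRU uses the Cho update
  `h_t = (1−z_t)h_{t−1} + z_t h̃_t`; the LSTM initializes the forget-gate
  bias at 1.
* **Hybrid units `[a, b]` mean [recurrent units, dense units]** — the
  hybrid stack has exactly one recurrent layer followed by one fully
  connected layer, so a two-valued units list can only refer to those two
  widths.
* **Max-pool size is 2** (smallest nontrivial); a feature map shorter than
  the pool is pooled whole so a lag-3 window with kernel 3 still flows
  through the stack.  Convolution is valid (unpadded); `kernel ≤ lag` is
  enforced at configuration time.
* **Dropout sits after the recurrent layer** (after the hidden dense layer
  for the plain CNN); **L2 weight decay** (`reg_rate`, convention
  `λ·Σw²`) applies to recurrent and dense kernels.  The search space fixes
  their magnitudes; their placement is this package's choice.
* **Loss is MSE, optimizer Adam** at learning rate 1e-3 (β₁ 0.9, β₂ 0.999,
  ε 1e-7), batch size 1, 20 epochs by default, samples shuffled per epoch
  from the run seed.  MSE matches RMSE reporting; Adam is the de-facto
  default for these layer types.

The engine in `gluforecast.nn` implements exactly these layers in numpy
with analytic gradients and backpropagation through time.  Correctness is
established by central-finite-difference gradient checks (relative
tolerance 1e-5) over every parameter of every layer type, including the
full conv→pool→GRU→dense chain, plus invariant tests: sigmoid gates in
(0, 1), ReLU outputs nonnegative, bit-identical repeated inference
(dropout inactive outside training), and monotone parameter counts.
Initialization is Glorot-uniform for input kernels and scaled-orthogonal
for recurrent kernels.  A NaN/inf epoch loss raises a divergence error
naming the epoch.

## Hyperparameter search

The per-architecture space: units 50–500 step 10 (two dimensions for
hybrids), dropout 0.1–0.9 continuous, L2 rate ∈ {0.01, 0.05, 0.005,
0.001}, filters ∈ {200, 128, 250}, kernel ∈ {3, 4} (conv models only).
Single-model units use the same 50–500 range: published winning
configurations for the single models fall outside any single fixed value,
so a range is the only self-consistent reading.  Published result tables
also contain occasional values outside the declared sets (reg rates 0.1,
0.006, 0.0001; dropout "02"/"03"); the declared space is kept as-is.

`bayes_optimize` seeds with `n_initial` (default 5) random configurations,
then fits a Gaussian-process surrogate (Matern ν=2.5 + white noise,
normalized y) to all finite-objective trials — integer dimensions scaled
to [0, 1], categoricals one-hot — and proposes each next trial by
maximizing expected improvement (ξ = 0.01) over 256 random candidates,
skipping already-evaluated configurations.  Failed (NaN) trials are
recorded but excluded from the surrogate.  Budget defaults to 20 trials.
The objective of `select_architecture` is validation RMSE in mmol/L on the
chronologically last 25% of the training partition — the test partition is
never touched during tuning.

## Synthetic CGM generator

`generate_cgm` emits, at fixed `interval_minutes` (default 15):

```
value(t) = clamp(baseline + circadian + meals + AR(1) noise, floor, ceiling)
```

with baseline 7 mmol/L, a 24-h sinusoid (default amplitude 0.8 mmol/L,
trough ≈ 03:00), meal excursions at 07:30/12:30/19:00 that rise instantly
and decay exponentially (mean 4 mmol/L, log-normal across days, decay 90
min), AR(1) Gaussian noise (innovation sd 0.25 mmol/L, coefficient 0.7 —
CGM sensor error is autocorrelated, and AR(1) is the simplest such model),
and a physiological clamp to [2, 25] mmol/L.  `inject_gaps` deletes index
ranges to emulate sensor dropouts.  The source trace behind the published
experiments is not redistributable, and its noise and gap statistics were
never characterized; these defaults are plausible for adult type-1 CGM
data, not calibrated to any dataset.

What passing on synthetic data shows: the pipeline is wired correctly, the
models can learn genuinely learnable temporal structure, tuning and
streaming behave as specified.  What it does not show: clinical accuracy on
real CGM data, robustness to real sensor artifacts (compression lows,
calibration jumps), or transfer across patients.

## Test and acceptance problem sizes

The verification experiments are sized to run comfortably on one CPU core:
sine-learnability uses a 500-point noiseless sine (lag 10, horizon 1,
CNN-GRU with 16 filters and 32/16 units, 20 epochs, 3 seeds; threshold
scaled RMSE < 0.1, pre-calibrated by an ordinary-least-squares reference
fit on the same windows).  The forecasting-skill check uses a 600-point
pure-AR(1) trace with coefficient 0.5, where the persistence baseline is
analytically √(2/(1+φ)) ≈ 1.15× the optimal one-step RMSE — a gap wide
enough to detect with ~150 test samples; both hybrids must beat
persistence in ≥ 2 of 3 seeds.  Bayesian-vs-random search is compared on
cheap analytic objectives (exhaustive recovery on a 6-point grid; paired
medians at budget 20 over 20 seeds).  These sizes are the package's own
verification design, scaled so the whole suite and acceptance script each
finish in minutes.

## Known limitations

* Single-sample (batch 1) numpy training is CPU-bound; configurations in
  the hundreds of units are usable but slow.  The defaults used by the
  untuned comparison runner are deliberately modest.
* No probabilistic/uncertainty outputs; point forecasts only.
* The streaming layer's broker is in-process; external brokers can
  implement the same publish/subscribe contract, but no network adapter is
  bundled.  Exactly-once delivery, persistence and dashboards are out of
  scope.
* Univariate only: no insulin, meal or activity covariates.
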