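# cropcast

Growth-trend forecasting and event-triggered irrigation scheduling for
greenhouse crops, built around the moisture-sensitive medicinal plant
*Panax notoginseng*.

Fixed-calendar irrigation ignores what the crop actually needs: too much or
too little water at the wrong growth stage slows growth or kills plants.
`cropcast` instead forecasts a normalised **growth status** signal from
hourly soil/air sensor streams and warns the grower 3–5 days before the
status is predicted to decline, so irrigation happens just before stress —
typically less often than a weekly schedule, with better outcomes. It is
aimed at precision-agriculture researchers and anyone who wants a fully
reproducible, desk-scale implementation of this class of pipeline.

## The model

The forecaster is an **Informer–LSTM–EWMA** stack:

1. **Informer** encoder–decoder for the long-horizon forecast (150 h).
   Self-attention is *ProbSparse*: each query is scored by the sparsity
   measure

   M(qᵢ, K) = maxⱼ (qᵢkⱼᵀ/√d) − (1/L_K) Σⱼ qᵢkⱼᵀ/√d

   and only the u = ⌈c·ln L_Q⌉ dominant queries (u = 26 at the operating
   point c = 5, L_Q = 164) receive full softmax attention,
   A(Q̄, K, V) = Softmax(Q̄Kᵀ/√d)V; the rest fall back to the time-mean of
   V. Between encoder layers a *distilling* stage
   (Conv1d → ELU → MaxPool, stride 2) halves the sequence length.
2. **LSTM** refinement of the predicted trajectory with the standard gate
   equations (fₜ, iₜ, oₜ = σ(w[hₜ₋₁,xₜ]+b); Cₜ = Cₜ₋₁⊙fₜ + iₜ⊙C̃ₜ;
   hₜ = oₜ⊙tanh Cₜ), added residually so an untrained refiner is the
   identity.
3. **EWMA** smoothing, Sₜ = αYₜ + (1−α)Sₜ₋₁, α = 0.3.

Upstream, sensor streams are screened with the 1.5·IQR Tukey fence,
gap-filled by linear interpolation, denoised with a σ = 10 Gaussian kernel,
and assembled into features (per-depth channels, layer differences,
adjacent-sensor means, min–max scaled to [0,1]). Downstream, a decline
detector finds the first sustained drop in the smoothed forecast; three
independently seeded runs are averaged and the mean onset becomes the
warning time. Outcome statistics (histogram probability densities with
normal overlays, Binᵢ = kᵢ/(K·L); survival growth rates) reproduce the
field-trial analytics.

Because no public dataset exists for these greenhouse streams, the package
includes a **synthetic greenhouse** generator (exponential soil-moisture
drydown with irrigation jumps, diurnal climate, a status signal that grows
inside the favourable moisture band and decays outside) with an exact truth
log, so every stage is testable end to end. Details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import cropcast as cc

# survival-count arithmetic from the field records
cc.percent_growth(10, 51)        # -> 410.0   (treated plot A1)
cc.percent_growth(23, 36)        # -> 56.5    (its internal control A2)
cc.percent_growth(36, 54)        # -> 50.0    (control group E1+E2)
cc.height_gap_percent(212, 174)  # -> 21.8    (% height gap, treated vs control)

# ensemble decision: three forecast runs whose declines start at 71/69/73 h
runs = []
for peak in (71, 69, 73):
    up = np.linspace(0.2, 0.9, peak + 1)
    down = 0.9 - 0.004 * np.arange(1, 150 - peak)
    runs.append(np.concatenate([up, down]))
bundle, decision = cc.ensemble_decide(runs, "2024-05-06 06:00")
bundle.per_run_onset_h           # -> [71, 69, 73]
bundle.ensemble_onset_h          # -> 71
print(decision.to_json())
```

prints

```json
{
  "origin": "2024-05-06 06:00:00",
  "warn_at": "2024-05-09 05:00:00",
  "lead_h": 71,
  "irrigation_volume_L": 85.0,
  "no_decline": false
}
```

i.e. the three repeated predictions average to 71 h, so data collected
through the morning of 6 May yield an irrigation warning for 9 May.

The full pipeline on synthetic data:

```bash
cropcast simulate --seed 2 --days 32 --out season/      # sensor + status CSV
cropcast run --seed 2 --out run/                        # preprocess -> train
                                                        # -> ensemble -> decide
cropcast loop --policy event --weeks 6 --seed 2 --out events.csv
```

`run/decision.json` carries the forecast origin, per-run onsets, ensemble
onset and calendar warning time; `events.csv` is the dated irrigation log
(the event-triggered policy typically fires 5 times over 6 weeks versus 6
for the fixed weekly schedule, while the simulated crop keeps growing).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch — simulate
a season from the seed, preprocess, train the three-run ensemble, forecast,
decide — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Pipeline artifacts (decision, QC counts, config manifest) land next to the
output file under `results/run_artifacts/`.
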