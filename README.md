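# ppgprv

A toolkit for low-cost wireless photoplethysmography (PPG) pulse-rate-variability
measurement and validation. It covers the complete path from raw (or simulated)
40 Hz PPG samples to ultra-short-term time-domain indicators and a paired
device-agreement analysis against an ECG reference:

- **`ppgprv.synthgen`** — ground-truthed synthetic recordings: AR(1)-plus-
  respiratory-sinusoid interval series with independently tunable SDNN/RMSSD,
  a two-lobe pulse template renderer, and Bernoulli (optionally bursty) sample
  dropout. Four scenario presets ship with the package: `sitting`,
  `sitting_deep_breathing`, `standing`, `supine`.
- **`ppgprv.preprocess`** — the conditioning chain: missing-slot interpolation,
  centered moving average, airPLS baseline correction, sixth-order Butterworth
  low-pass (18 Hz default, zero-phase offline / causal streaming), and the
  second derivative (APG).
- **`ppgprv.beat_detection`** — windowed threshold decision rule on the APG
  (20 s windows, per-window adaptive quantile or fixed threshold, refractory
  suppression), peak-to-peak interval extraction, interval outlier cleaning.
- **`ppgprv.prv_metrics`** — mean HR, mean IBI, SDNN, RMSSD (standard and
  literal N−2 variants) and the missing-sample data-loss percentage.
- **`ppgprv.agreement_stats`** — difference factor (DF%), percentage bias,
  RMSE, Bland–Altman limits of agreement, OLS regression with R²,
  Shapiro-gated paired t / Wilcoxon tests, Levene-gated two-way ANOVA vs.
  Scheirer–Ray–Hare on ranks, and Tukey / Dunn post hoc comparisons.
- **`ppgprv.io` / `ppgprv.cli`** — `t_s,ppg` CSV signals, RR interval text
  files (one ms value per line), cohort CSVs, YAML run configuration, and a
  four-command CLI.

## CLI

```sh
# synthesize a 3-minute sitting recording with ~1% dropout
ppgprv simulate --scenario sitting --seed 1 -o ppg.csv --truth rr_truth.txt

# full pipeline: filter -> APG -> beat detection -> PRV summary
ppgprv process ppg.csv --rr-out rr_est.txt --summary-out summary.json

# indicator deltas between two interval files
ppgprv compare rr_truth.txt rr_est.txt -o agreement.json

# cohort-level agreement workflow (CSV: subject_id,scenario,indicator,ecg_value,ppg_value)
ppgprv cohort cohort.csv -o report/
```

All randomness is controlled by `--seed`; identical seeds give byte-identical
outputs.

## Library example

```python
from ppgprv import PRESETS, simulate_recording, detect_events, pp_intervals, summarize
from ppgprv.preprocess import preprocess_signal

signal, truth_ibi, truth_idx = simulate_recording(PRESETS["supine"], seed=7)
apg = preprocess_signal(signal)
ibi = pp_intervals(detect_events(apg))
print(summarize(ibi, signal))
```
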