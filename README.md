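# emgait

Surface-EMG gait analysis pipeline for patient-reported knee-osteoarthritis
severity: raw EMG preprocessing, gait-cycle envelope normalization,
co-contraction-index and fiducial feature extraction, WOMAC/VAS midpoint-rule
severity categorization, random-forest severity regression, and exact Shapley
feature attribution. A synthetic cohort generator provides reproducible raw
data with the statistical structure the analysis assumes, so every stage is
testable end-to-end without any external dataset.

## Pipeline

1. **synthetic** (`emgait.synthetic`) — cohort of subjects with a latent
   severity in [0, 1]; per limb, raw 1500 Hz 4-channel EMG trials
   (band-limited carrier amplitude-modulated by severity-dependent muscle
   activation templates, 60 Hz line noise, low-SNR artifact epochs), gait
   events, temporospatial variables, and WOMAC/VAS records linked to severity.
2. **preprocess** (`emgait.preprocess`) — 20–450 Hz band-pass, 60 Hz notch,
   per-cycle SNR gating at 18 dB against a quiet-baseline reference,
   full-wave rectification, 6 Hz low-pass linear envelope, time normalization
   to 101 points per gait cycle, averaging across trials, and per-muscle
   amplitude normalization to the maximum of the averaged waveform.
   All filters run forward–backward (zero-phase), so the design orders
   (4th-order band-pass, 2nd-order low-pass) double in effect.
3. **features** (`emgait.features`) — per-window (full/stance/swing) mean,
   max, min, peak latencies and AUC per muscle, plus the co-contraction index
   CCI(t) = (EMG_L/EMG_H)(EMG_L + EMG_H) for the TA–G, RF–MH, TA–MH and RF–G
   pairs, windowed as the mean over the inclusive sample range; one feature
   row per limb.
4. **prom** (`emgait.prom`) — WOMAC subscale/total scoring, three-way severity
   categorization with midpoint cut-offs (1.5·n, 2.5·n ⇒ 36/60 for the
   24-item total; VAS cut-offs 3.75/6.25 as an implementation default),
   one-way ANOVA, Welch t-tests, ensemble waveforms with 95% CIs.
5. **model** (`emgait.model`) — 80/20 split (grouped by subject by default),
   top-15 univariate-F feature selection and max_depth tuning by 5-fold CV on
   the training portion only, random-forest regression per PROM target
   (WOMAC total, pain, stiffness, physical function, VAS).
6. **shapley** (`emgait.shapley`) — interventional Shapley values via exact
   subset enumeration (≤ 15 features) and an exact tree-path algorithm for
   forests; global mean-|SHAP| importance and a direction-of-effect summary.

## CLI

```bash
emgait run --seed 1 --out out/                 # full pipeline
emgait simulate --seed 1 --out data/           # synthetic cohort artifacts
emgait features --seed 1 --out features.csv    # simulate + preprocess + features
emgait severity --prom data/prom.csv --out labels.csv
emgait fit --features features.csv --out report/
```

All subcommands accept `--config config.yaml` (see `emgait.config.RunConfig`
for the schema); every source of randomness flows from the single seed.

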