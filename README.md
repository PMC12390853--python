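# trimanus

Offline simulator and stream-processing library for hybrid gaze–EEG–manual
("tri-manual") virtual-hand control studies. The package generates seeded
synthetic multimodal sessions — single-channel EEG (512 Hz), gaze (120 Hz),
controller poses (90 Hz) — and runs them through the full control stack:

- **`synthetic`** — ground-truth-annotated session generation: band-structured
  EEG with attention-modulated beta/alpha power, blink and muscle artifacts,
  fixation–saccade gaze with Gaussian observation noise, minimum-jerk reaches.
- **`eeg`** — artifact detection (±100 µV amplitude, 50 µV/sample gradient,
  35 µV variance thresholds with 500 ms blanking), 4th-order Butterworth
  band-pass (4–40 Hz) + 500 ms moving-average detrend, Welch spectra
  (256-point FFT, Hamming, 50% overlap), θ/α/β band powers, the β/(α+θ)
  attention metric with a 30-s rolling baseline, 0–200 quality index,
  10-dimensional feature frames at 8 Hz, 3.75-s epoch segmentation, and
  ERD/ERS band-power time courses.
- **`gate`** — the three-tier false-trigger cascade: 300 ms temporal
  consistency (quality < 150 resets), quality-scaled thresholds (+20% below
  100, disabled below 50), 2.5 σ contextual outlier rejection over a 60-s
  buffer, plus artifact blanking and a 1-s refractory period.
- **`gaze`** — constant-velocity Kalman filtering of noisy gaze
  (process SD 0.1, observation SD 0.5 deg), 45° cone target ranking and
  locking, PD gaze stabilization (damping 0.65–0.85), and fixation-map
  entropy.
- **`arbitration`** — softmax control-authority weighting over the
  {manual, virtual} channels with manual priority on spatial overlap and
  handover-latency accounting.
- **`load`** — Matérn-3/2 Gaussian-process workload prediction with the
  >68/100 intervention rule (threshold ×1.2, 0.4 m/s speed cap, 2.5 N/mm
  stabilizing stiffness; hysteresis release at 63) and the weighted
  task-complexity score.
- **`world`** — kinematic three-sphere scene simulation (equilateral
  triangle, 0.40 m sides) with the 5 mm / 1 s success rule and the objective
  trial metrics (spatial error, trajectory efficiency, log dimensionless
  jerk, velocity cross-correlation).
- **`evaluate`** — study summaries, directional improvement percentages,
  paired t / Wilcoxon comparisons with Bonferroni-adjusted α = 0.05/6, and
  consistency checks of published reference tables.

## CLI

```sh
trimanus simulate --config cfg.yaml --seed 1 --out session/   # synthesize a session
trimanus features session/ --out feats/                       # 8 Hz feature table
trimanus gate feats/run-01_features.tsv --out events.tsv      # activation events
trimanus gaze session/ --out gaze/                            # Kalman-filtered gaze
trimanus run --config cfg.yaml --trials 5 --out study/        # simulate both conditions
trimanus evaluate study/ --out report/                        # metrics table
trimanus load fit study.tsv --out model.json                  # workload model
trimanus report                                               # printed-value checks
```

Session files are plain TSV sample tables with JSON sidecars under
`sub-XX/sub-XX_task-trimanual_run-YY_{eeg,gaze,pose,events}.tsv`; floats are
written at 17 significant digits so identical seeds produce byte-identical
files.

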