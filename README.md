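# fogkit

Real-time **freezing-of-gait (FOG) detection** and gait metrics from
lower-leg inertial sensors.

FOG is an episodic inability to initiate or continue walking that affects
many people with Parkinson's disease. A leg-worn device that detects a
freeze as it happens can deliver a rhythmic somatosensory cue (vibration at
roughly the wearer's natural step rate) to help walking resume — but only
if detection is accurate and cheap enough to run per-sample on a
microcontroller. `fogkit` implements that detection and measurement stack
as a Python library with a thin CLI, together with a synthetic gait
generator so the entire pipeline is testable with exact ground truth and no
external data.

## What it computes

**Window features.** For each accelerometer axis over sliding 256-sample
windows (~2.5 s at 100 Hz):

- *freeze index* `FI = P[3–8 Hz] / P[0.5–3 Hz]` — the ratio of "freeze
  band" (trembling) to "walking band" (locomotor) spectral power;
- *band power* `P[0.5–8 Hz]` — distinguishes standing still (low power)
  from trembling (high FI **and** high power);
- variance, L1 norm, L2 norm of acceleration, and the spectral entropy of
  the in-band periodogram.

Features are available in a batch path (windowed FFT) and a streaming path
using a **sliding DFT**: per sample, each tracked bin updates as
`X_k ← (X_k − x_oldest + x_new)·e^{2πik/N}`, costing O(tracked bins)
instead of an FFT per window — the property that makes per-sample detection
feasible on embedded hardware. Both paths agree to 1e-9 and are checked
against each other continuously.

**Classifier.** A random forest (25 trees, maximum depth 15, pruning
enabled) whose cost function weights false negatives (missed FOG) 10×
heavier than false positives, reflecting the strong class imbalance of
freezing versus walking. Evaluation uses leave-one-subject-out (LOSO)
cross-validation with window-level sensitivity/specificity and a
threshold-swept ROC.

**Gait metrics.** Gyroscope peak detection for steps; step frequency
(strikes/min); a step symmetry index (0 = perfectly alternating left/right
timing); stride length by doubly integrating horizontal acceleration over
each gait cycle with a zero-velocity update (ZUPT) at foot strikes to
cancel integration drift; freeze counts/durations from observer event logs
or detector output; between-observer %CV.

**Closed-loop simulation.** A causal streaming engine replays a recording
sample-by-sample and drives a cue controller: responsive mode triggers
after a debounced run of FOG predictions and stops a few seconds after
walking resumes; continuous mode cues throughout.

## Worked example

```bash
python examples/01_detect_fog.py
```

```
synth-1: 2 FOG episodes, 368 feature windows
synth-2: 1 FOG episodes, 368 feature windows
synth-3: 0 FOG episodes, 368 feature windows

LOSO mean sensitivity 96.6%, mean specificity 99.8%, AUC 1.000
```

Three synthetic subjects are generated (walking with trembling/akinetic
freezing episodes), features extracted, and each subject scored by a forest
trained only on the other two. Sensitivity is the fraction of FOG windows
detected; specificity the fraction of normal walking left uncued. The other
examples cover stride-length estimation under sensor bias
(`02_stride_length.py`), closed-loop responsive cueing with the per-sample
operation budget (`03_responsive_cueing.py`), and observer-log gait metrics
(`04_observer_metrics.py`).

The same pipeline is exposed as a CLI:

```bash
fogkit simulate --out run/ --seed 1 --duration 120
fogkit extract-features --in run/recording.csv --hop 32 --out run/features.csv
fogkit gait-metrics --recording run/recording.csv --events run/events.csv --out run/gait.json
```

## Layout

```
src/fogkit/
  core.py       recordings, labels, event logs (validated containers)
  synthetic.py  gait/FOG signal generator with exact ground truth
  io.py         native CSV + Daphnet-style annotated format, feature files
  features.py   freeze index, band power, entropy; batch FFT + sliding DFT
  detector.py   cost-weighted random forest, LOSO, ROC, JSON model export
  metrics.py    steps, symmetry, stride length (ZUPT), freeze metrics, %CV
  realtime.py   causal streaming engine + responsive/continuous cueing
  cli.py        subcommands over the library
```

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
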