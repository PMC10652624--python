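# Methods

This note documents the models, numerical conventions and design choices
behind `fogkit`, and what the synthetic experiments do and do not
demonstrate about real data.

## Spectral features

All per-window features are computed per accelerometer axis on 256-sample
rectangular windows (~2.5 s at the default 100 Hz). The periodogram is
one-sided with `P_k = |X_k|²/N²` at DC/Nyquist and `2|X_k|²/N²` elsewhere,
so full-spectrum power equals the window mean square (Parseval); this
normalisation is asserted on every random window in the tests.

- **Band membership** of a DFT bin is decided by its centre frequency
  `k·fs/N` with half-open intervals `[f1, f2)`: 3 Hz belongs to the freeze
  band, so walking band [0.5, 3) and freeze band [3, 8) never double-count.
  The total band [0.5, 8] is upper-inclusive.
- **Freeze index** is freeze-band power over walking-band power with the
  denominator floored at `epsilon_power = 1e-8 (m/s²)²` — below any real
  accelerometer noise floor. The floor prevents infinities when the wearer
  stands still; it deliberately does not hide stillness, which the separate
  band-power feature identifies.
- **Variance** uses divisor N (population form); L1/L2 norms act on the
  raw, un-centred window. Features are computed on acceleration only; the
  gyroscope is reserved for step detection.
- **Spectral entropy** is the Shannon entropy (nats) of the periodogram
  normalised over the total-band bins. The alternative (sample entropy) is
  deliberately isolated behind this one named function so it could be
  swapped without touching callers. A zero-power window returns the maximum
  `ln(n_bins)` by convention: an empty spectrum is uninformative. Note that
  an off-bin tone spreads over two bins (entropy near ln 2 rather than 0),
  and broadband noise sits ~0.4 nats below the maximum — both are
  properties of the periodogram, not defects.

### Sliding DFT

The streaming path maintains the tracked bins (all total-band bins, 19 at
fs = 100 Hz) with the per-sample recurrence
`X_k ← (X_k − x_oldest + x_new)·e^{2πik/N}`, plus O(1) running sums for the
time-domain features. Floating-point drift is bounded by recomputing the
coefficients directly from the buffered window every 4096 updates
(`renorm_interval`); between renormalisations the drift stays far below the
1e-6 relative tolerance asserted against a direct DFT at every step of a
10,000-sample stream. The rectangular window is the price of the
recurrence: no taper admits a per-sample update. Cost is counted in
arithmetic operations (`8·n_bins + 8` per sample per axis plus the
amortised renormalisation), asserted to be independent of stream length and
far below an FFT per sample — operation counts rather than wall-clock,
since microsecond timings are hardware-specific.

Batch extraction (vectorised FFT) and the streaming path produce identical
features to 1e-9 relative; `replay_equivalence` re-checks this
window-for-window through the classifier, and a fault-injection hook
verifies the check actually detects corrupted streaming state.

## Window labelling and the classifier

Windows inherit the majority of their per-sample labels; ties resolve
toward FOG (a detector that must not miss freezes should treat an
ambiguous window as positive), then no-FOG, then unannotated. Unannotated
samples (Daphnet code 0) are excluded from training and from
sensitivity/specificity denominators but flow through streaming detection.
The training hop is 32 samples (windows overlap 87.5%), a compromise
between sample count and window decorrelation; streaming prediction uses
hop 1.

The forest: 25 trees, maximum depth 15 (reading the "maximum size" of a
fast binary tree as a depth cap; both knobs are config), minimal
cost-complexity pruning `ccp_alpha = 1e-4`, and the 10× false-negative cost
implemented as class weights — the expected-loss-equivalent mechanism when
only the cost ratio is specified. Training rows are put in canonical
lexicographic order before fitting so the model is invariant to how
subjects' windows were concatenated; with a fixed seed the whole pipeline
is bit-reproducible.

Evaluation is leave-one-**subject**-out: window-level cross-validation
would leak nearly identical neighbouring windows between train and test.
Per-subject sensitivity/specificity are averaged with undefined metrics
(e.g. a held-out subject with no FOG) flagged and excluded, not
zero-filled. The ROC sweeps unique pooled probabilities (always including
(0,0) and (1,1)) with trapezoidal AUC; it is cross-checked against
scikit-learn's AUC in the tests. Event-level scoring (merging window runs
into episodes) is available via `merge_prediction_intervals` but
window-level metrics are primary.

## Gait metrics

- **Step detection**: peaks of the smoothed (moving average, halfwidth 5
  samples) gyro axis — by default the axis with the largest variance —
  above 50 deg/s and at least 0.25 s apart. All thresholds are config; the
  defaults were chosen for shank-worn sensors where swing-phase angular
  velocity reaches a few hundred deg/s.
- **Symmetry index**: step intervals are strike→opposite-side-strike times;
  the index is `|mean(L→R) − mean(R→L)| / ((mean(L→R)+mean(R→L))/2)`. The
  balanced-mean denominator keeps the worked value 0.1818… for the 0.5 s /
  0.6 s case regardless of whether the walk ends mid-cycle; alternative
  normalisations would differ only at the third decimal for typical gait.
- **Stride length**: per gait cycle (consecutive same-side strikes),
  horizontal acceleration is trapezoid-integrated to velocity; the ZUPT
  constraint sets velocity to zero at both strikes (the foot is in stance),
  so the residual end velocity is attributed to drift and removed as a
  linear ramp before the second integration. A constant accelerometer bias
  is cancelled *exactly* by this linear detrend; slowly varying bias is
  cancelled to first order. For recordings of unknown orientation a
  documented heuristic (0.1 Hz low-pass gravity estimate subtracted,
  dominant residual axis taken) stands in for the known horizontal axis of
  the synthetic trajectories.
- **Freeze metrics** count intervals, sum durations and express them as a
  percentage of the circuit completion time; detector tracks are first
  merged with a gap tolerance of 1 window. **%CV** is `100·sd/mean`
  (sample sd) per trial, averaged over trials.

## Synthetic generator

The generator emulates the statistical structure the detector relies on,
not biomechanics:

- **Walking**: per axis, a sinusoid at the step fundamental
  (100 steps/min → 1.67 Hz) plus two harmonics with amplitude decay 0.25,
  default amplitude 2 m/s². The decay keeps ≥ 90% of in-band power below
  3 Hz even though the second harmonic (3.3 Hz) falls inside the freeze
  band — as real locomotor harmonics do. Gyro: Gaussian angular-velocity
  pulses (σ = 50 ms, 200 deg/s) at each step; steps alternate sides on a
  regular grid at the step frequency.
- **FOG episodes**: onsets Poisson (1/min), durations log-normal
  (mean 8 s, sd 4 s), at least 1 s of walking between episodes; 70%
  trembling (5 Hz oscillation, 1.5 m/s²), 30% akinetic (movement ≈ sensor
  noise only). Both modes are labelled FOG, as annotation protocols do not
  distinguish them. White Gaussian sensor noise, sd 0.15 m/s² (accel).
- **Trajectory mode**: stance for half of each 1.2 s cycle, then a
  minimum-jerk swing covering the cycle's stride (1.2 ± 0.1 m); the
  accelerometer reads the analytic second derivative, so the ground truth
  is exact and independent of any injected bias.

Defaults are plausibility choices for moderate parkinsonian gait, fixed
once; they are the package's test conditions, not fits to any cohort.

**What passing tests show — and don't.** The synthetic freeze/walk classes
are spectrally well separated, so near-ceiling LOSO accuracy demonstrates
the pipeline (features → cost-weighted forest → LOSO protocol) is correct,
not that real-world FOG detection reaches those numbers: real freezes have
variable tremble frequency and amplitude, turning and postural artefacts,
inter-subject morphology differences, and annotation latency, all absent
here. The permutation control (shuffled labels → AUC ≈ 0.5) confirms the
evaluation cannot manufacture accuracy. Conversely the stride-length bound
is meaningful as stated: a constant bias injection is exactly the failure
mode ZUPT drift correction targets.

## Cue controller

Responsive mode triggers after 3 consecutive FOG-predicted windows
(debounce, config) and stops `stop_delay = 3 s` after the first non-FOG
prediction of a resumed walk; FOG recurring within the stop delay extends
the same cue interval rather than retriggering. Continuous mode cues from
warm-up to stream end. The original responsive cue was human-triggered;
the debounce rule is this package's automated stand-in and is labelled as
such. Both legs are cued together by default; per-leg addressing exists in
the config.

Detection latency in responsive mode is bounded by (window length +
debounce·hop)/fs — about 2.6 + 1 s at hop 32 — because a window must fill
with freeze content before its features reflect the episode. Reducing the
hop to 1 (the streaming default) trims the debounce term but not the
window-fill term.

## Numerical and edge-case conventions

- Timestamps are float seconds internally; Daphnet milliseconds and
  milli-g are converted on read (g = 9.80665 m/s²).
- Readers reject malformed input with the offending row; writers
  round-trip losslessly (17 significant digits, round-trip float parsing).
- A recording shorter than one window yields an empty feature set with a
  warning; an unwarmed streaming extractor refuses to emit features.
- Freeze intervals outside the completion window are clipped with a
  warning; zero-length merged intervals are kept as zero-duration events.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical configs give bit-identical outputs.

## Problem sizes

The shipped experiments use 6 synthetic subjects × 10 min at 100 Hz
(~11,000 windows at hop 32) for the detection objective, and 50 gait
cycles for the stride experiment — large enough for stable window-level
rates (≈ 250 FOG windows per subject) while keeping any run to seconds.

## Known limitations

- No turning, posture change, or sit/stand transitions in the generator;
  the features' robustness to those is untested here.
- Single-sensor: no bilateral fusion, although event logs carry both
  sides.
- The Daphnet-style reader keeps only the ankle acceleration channels and
  assumes the documented column order and milli-g units.
- The entropy variant is spectral; sample entropy would need a different
  streaming formulation.
- Stride estimation assumes the instrumented foot is stationary at each
  same-side strike; festinating gait with incomplete foot placement
  violates this and would degrade the ZUPT.
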