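"""Gait metrics from an observer-style event log.

Builds a keystroke-style event log (foot strikes, freeze start/end, segment
markers) from synthetic ground truth and computes the circuit metrics:
step frequency, step symmetry, freeze count/duration, and the
between-observer coefficient of variation.
"""

from fogkit import (
    SyntheticConfig,
    generate_event_log,
    generate_recording,
    observer_cv,
    summarize,
)

cfg = SyntheticConfig(duration=60.0, seed=5)
recording, truth = generate_recording(cfg)

# three observers with 50 ms keystroke jitter each
logs = [
    generate_event_log(
        cfg, truth, jitter_sd=0.05, observer_id=f"obs{i}", jitter_seed=i
    )
    for i in range(3)
]
summaries = [summarize(log) for log in logs]

for log, s in zip(logs, summaries):
    print(
        f"{log.observer_id}: step freq {s.step_frequency:5.1f}/min, "
        f"symmetry {s.symmetry_index:.3f}, "
        f"{s.freeze_count} freezes, {s.cumulative_freeze_time:.1f} s frozen "
        f"({s.freeze_time_fraction:.1f}% of circuit)"
    )

cv_freq = observer_cv([s.step_frequency for s in summaries])
cv_sym = observer_cv([s.symmetry_index for s in summaries])
print(
    f"\nbetween-observer %CV: step frequency {cv_freq:.2f}%, "
    f"symmetry index {cv_sym:.1f}%"
    "\n(count-based metrics are nearly immune to keystroke jitter, while"
    "\ntiming-ratio metrics like the symmetry index inherit much more"
    "\nobserver variability — the same pattern video annotation shows)"
)
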