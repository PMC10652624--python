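"""Streaming detection pipeline and simulated closed-loop cue controller.

``stream`` drives the per-sample path an embedded device would run: each new
IMU sample updates the sliding-DFT feature state in O(tracked bins); once
the window is warm, a feature vector is emitted per window position, the
forest scores it, and the cue controller reacts.

Cueing modes mirror the study protocol: *responsive* cueing starts a
rhythmic vibration after a debounced run of FOG predictions and stops a few
seconds after walking resumes; *continuous* cueing runs for the whole
stream.  The original responsive cue was human-triggered; the debounce rule
(default 3 consecutive FOG windows) is this package's automated stand-in for
the observer's judgement and is configurable.

The budget report counts arithmetic operations per sample rather than
wall-clock time, so the constant-cost-per-sample contract of the sliding
DFT can be asserted portably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import ImuRecording, ValidationError
from .detector import FogModel, FogPredictionTrack, PortableForest
from .features import (
    DEFAULT_BANDS,
    BandDefinition,
    StreamingFeatureExtractor,
    extract_features,
)


@dataclass(frozen=True)
class CueConfig:
    """Cue-controller settings.

    ``cue_frequency`` is the rhythm of the vibration bursts, set near the
    wearer's natural step rate; ``stop_delay`` keeps the responsive cue on
    for a few seconds after walking resumes; ``min_consecutive_fog_windows``
    debounces the automated trigger against isolated false positives.
    """

    mode: str = "responsive"  # none | responsive | continuous
    cue_frequency: float = 100.0 / 60.0  # Hz
    cue_intensity: float = 1.0
    stop_delay: float = 3.0
    min_consecutive_fog_windows: int = 3
    legs: str = "both"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "responsive", "continuous"):
            raise ValidationError(f"unknown cue mode {self.mode!r}")
        if self.stop_delay < 0:
            raise ValidationError("stop_delay must be >= 0")
        if self.min_consecutive_fog_windows < 1:
            raise ValidationError("debounce must be >= 1 window")


@dataclass
class CueTrace:
    """Active cueing intervals and the events that triggered them."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    trigger_events: list[tuple[float, str]] = field(default_factory=list)


class _ResponsiveController:
    """Debounced on / delayed off state machine for responsive cueing."""

    def __init__(self, config: CueConfig) -> None:
        self.config = config
        self.fog_run = 0
        self.cue_on = False
        self.cue_start: float | None = None
        self.pending_off: float | None = None
        self.trace = CueTrace()

    def step(self, t: float, is_fog: bool) -> None:
        c = self.config
        if is_fog:
            self.fog_run += 1
            self.pending_off = None  # walking has not resumed after all
            if not self.cue_on and self.fog_run >= c.min_consecutive_fog_windows:
                self.cue_on = True
                self.cue_start = t
                self.trace.trigger_events.append((t, "fog_onset"))
        else:
            self.fog_run = 0
            if self.cue_on and self.pending_off is None:
                self.pending_off = t + c.stop_delay
        if (
            self.cue_on
            and self.pending_off is not None
            and t >= self.pending_off
        ):
            self.trace.intervals.append(
                (self.cue_start, self.pending_off, c.legs)
            )
            self.cue_on = False
            self.cue_start = None
            self.pending_off = None

    def finish(self, t_end: float) -> CueTrace:
        if self.cue_on:
            end = (
                self.pending_off
                if self.pending_off is not None and self.pending_off <= t_end
                else t_end
            )
            self.trace.intervals.append(
                (self.cue_start, end, self.config.legs)
            )
        return self.trace


def run_cue_controller(
    times: np.ndarray,
    is_fog: np.ndarray,
    config: CueConfig,
    t_end: float | None = None,
) -> CueTrace:
    """Apply the cue state machine to a causal prediction sequence."""
    t_end = float(times[-1]) if t_end is None and len(times) else t_end
    if config.mode == "none" or len(times) == 0:
        return CueTrace()
    if config.mode == "continuous":
        trace = CueTrace(
            trigger_events=[(float(times[0]), "continuous_start")]
        )
        trace.intervals.append((float(times[0]), t_end, config.legs))
        return trace
    ctl = _ResponsiveController(config)
    for t, f in zip(times, is_fog):
        ctl.step(float(t), bool(f))
    return ctl.finish(t_end)


def stream(
    recording: ImuRecording,
    model: FogModel | PortableForest,
    bands: BandDefinition = DEFAULT_BANDS,
    cue_config: CueConfig = CueConfig(),
    hop: int = 1,
    fault_hook: Callable[[int, StreamingFeatureExtractor], None] | None = None,
) -> tuple[FogPredictionTrack, CueTrace, dict]:
    """Run the causal per-sample pipeline over a recording.

    Samples are consumed strictly in order with no lookahead; a feature
    vector is emitted every ``hop`` samples once ``window_length`` samples
    have been seen.  The classifier is stateless, so the emitted windows are
    scored in vectorized chunks — numerically identical to scoring each
    window as it appears — and the cue controller consumes the predictions
    in causal order.  ``fault_hook(window_index, extractor)`` is a test hook
    for corrupting streaming state.

    Returns the prediction track, the cue trace, and an operation-count
    budget report.
    """
    n = bands.window_length
    ext = StreamingFeatureExtractor(recording.sampling_rate, bands)
    ends = np.arange(n - 1, len(recording), hop)
    want = set(ends.tolist())
    rows, times = [], []
    widx = 0
    for i in range(len(recording)):
        ext.update(recording.accel[i])
        if i in want:
            if fault_hook is not None:
                fault_hook(widx, ext)
            rows.append(ext.features())
            times.append(recording.time[i])
            widx += 1
    if not rows:
        raise ValidationError("recording shorter than one feature window")
    matrix = np.vstack(rows)
    times = np.asarray(times)
    proba = model.predict_proba(matrix)
    thr = model.config.decision_threshold
    pred = proba >= thr
    track = FogPredictionTrack(
        window_end_times=times,
        probabilities=proba,
        labels_pred=pred,
        labels_true=None,
        threshold=thr,
    )
    trace = run_cue_controller(
        times, pred, cue_config, t_end=float(recording.time[-1])
    )
    budget = ext.op_counts()
    budget["windows_emitted"] = len(rows)
    budget["hop"] = hop
    return track, trace, budget


def replay_equivalence(
    recording: ImuRecording,
    model: FogModel | PortableForest,
    bands: BandDefinition = DEFAULT_BANDS,
    hop: int = 32,
    tolerance: float = 1e-9,
    fault_hook: Callable[[int, StreamingFeatureExtractor], None] | None = None,
) -> dict:
    """Check that streaming and batch prediction paths agree window-for-window.

    Returns a report with ``equivalent`` (bool), the maximum absolute
    probability deviation, and the first divergent window if any.
    """
    n_windows = (len(recording) - bands.window_length) // hop + 1
    if n_windows < 10:
        raise ValidationError(
            "recording too short: need >= 10 windows for a replay check"
        )
    batch = extract_features(recording, bands, hop=hop, mode="batch")
    p_batch = model.predict_proba(batch.matrix)
    track, _, _ = stream(
        recording, model, bands, CueConfig(mode="none"), hop=hop,
        fault_hook=fault_hook,
    )
    m = min(len(p_batch), len(track.probabilities))
    diff = np.abs(p_batch[:m] - track.probabilities[:m])
    bad = np.nonzero(diff > tolerance)[0]
    return {
        "equivalent": bad.size == 0 and len(p_batch) == len(track.probabilities),
        "n_windows": int(len(p_batch)),
        "n_windows_stream": int(len(track.probabilities)),
        "max_abs_diff": float(diff.max()) if m else 0.0,
        "first_divergent_window": int(bad[0]) if bad.size else None,
        "tolerance": tolerance,
    }
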