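"""Gait metrics from IMU signals and from observer event logs.

IMU side: steps are detected as peaks of the (smoothed) shank angular
velocity; stride length is obtained by doubly integrating horizontal
acceleration over each gait cycle (strike to next same-side strike) with a
zero-velocity update (ZUPT) at the cycle boundaries — the foot is stationary
in stance, so any residual end-of-cycle velocity is integration drift and
the implied linear velocity trend is subtracted before the second
integration.  A constant accelerometer bias is removed exactly by this
linear detrend.

Annotation side: step frequency (foot strikes per minute), a step symmetry
index (0 = perfectly alternating, equal left/right timing), freeze
counts/durations/time fraction over a completion window, and the percentage
coefficient of variation between observers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import GaitEventLog, ImuRecording, ValidationError
from .detector import FogPredictionTrack


@dataclass(frozen=True)
class StepDetectionConfig:
    """Peak-detection settings for gyroscope step detection."""

    min_peak_height: float = 50.0  # deg/s
    min_inter_peak_interval: float = 0.25  # s
    smoothing_halfwidth: int = 5  # samples, moving average
    axis_selection: str = "max_variance"  # or "x"/"y"/"z"

    def __post_init__(self) -> None:
        if self.min_inter_peak_interval <= 0:
            raise ValidationError("min_inter_peak_interval must be > 0")
        if self.smoothing_halfwidth < 0:
            raise ValidationError("smoothing_halfwidth must be >= 0")


@dataclass
class GaitSummary:
    """Derived gait metrics for one circuit/segment."""

    step_count: int
    step_frequency: float  # steps/min
    symmetry_index: float | None
    stride_lengths: np.ndarray
    mean_stride_length: float | None
    freeze_count: int
    cumulative_freeze_time: float  # s
    freeze_time_fraction: float  # % of completion time
    completion_time: float  # s


_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def detect_steps(
    recording: ImuRecording,
    config: StepDetectionConfig = StepDetectionConfig(),
) -> np.ndarray:
    """Step times from peaks of the smoothed gyro axis."""
    if recording.gyro is None:
        raise ValidationError("no gyroscope channels in recording")
    if config.axis_selection == "max_variance":
        axis = int(np.argmax(recording.gyro.var(axis=0)))
    else:
        axis = _AXIS_INDEX[config.axis_selection]
    sig = recording.gyro[:, axis]
    h = config.smoothing_halfwidth
    if h > 0:
        kernel = np.ones(2 * h + 1) / (2 * h + 1)
        sig = np.convolve(sig, kernel, mode="same")
    distance = max(
        1, int(round(config.min_inter_peak_interval * recording.sampling_rate))
    )
    peaks, _ = find_peaks(
        sig, height=config.min_peak_height, distance=distance
    )
    return recording.time[peaks]


def step_frequency(
    steps: np.ndarray | GaitEventLog, duration: float
) -> float:
    """Steps per minute: count / duration * 60 (both sides pooled)."""
    if duration <= 0:
        raise ValidationError("duration must be positive")
    if isinstance(steps, GaitEventLog):
        count = len(steps.strike_times())
    else:
        count = len(np.asarray(steps))
    return count / duration * 60.0


def symmetry_index(log: GaitEventLog) -> float:
    """Timing asymmetry between alternating steps; 0 = perfect symmetry.

    A step interval is the time from one strike to the next opposite-side
    strike; the index is |mean(left-initiated) - mean(right-initiated)|
    divided by the balanced mean (mean_LR + mean_RL)/2, so a surplus of
    intervals on one side (a walk ending mid-cycle) does not skew the
    denominator.
    """
    left = log.strike_times("left")
    right = log.strike_times("right")
    if len(left) < 2 or len(right) < 2:
        raise ValidationError(
            "symmetry index undefined: need >= 2 strikes per side"
        )
    strikes = sorted(
        [(t, "left") for t in left] + [(t, "right") for t in right]
    )
    lr, rl = [], []
    for (t0, s0), (t1, s1) in zip(strikes, strikes[1:]):
        if s0 == s1:
            continue  # same-side double strike: not an alternating step
        (lr if s0 == "left" else rl).append(t1 - t0)
    if not lr or not rl:
        raise ValidationError(
            "symmetry index undefined: no alternating intervals"
        )
    m_lr, m_rl = np.mean(lr), np.mean(rl)
    return float(abs(m_lr - m_rl) / (0.5 * (m_lr + m_rl)))


def _gravity_removed_horizontal(
    recording: ImuRecording, cutoff: float = 0.1
) -> np.ndarray:
    """Dominant horizontal acceleration after low-pass gravity removal.

    Heuristic for real recordings of unknown orientation: estimate gravity
    per axis as a 0.1 Hz low-pass (moving average) and take the residual
    axis with the largest variance.
    """
    fs = recording.sampling_rate
    span = max(3, int(round(fs / cutoff)) | 1)
    kernel = np.ones(span) / span
    resid = np.empty_like(recording.accel)
    for ax in range(3):
        grav = np.convolve(recording.accel[:, ax], kernel, mode="same")
        resid[:, ax] = recording.accel[:, ax] - grav
    return resid[:, int(np.argmax(resid.var(axis=0)))]


def stride_length(
    recording: ImuRecording,
    step_times: np.ndarray,
    axis: str | None = "x",
) -> np.ndarray:
    """Per-cycle stride lengths by drift-corrected double integration.

    ``step_times`` are same-side foot strikes; each consecutive pair bounds
    one gait cycle.  Horizontal acceleration is integrated (trapezoid rule)
    to velocity; the ZUPT constraint forces velocity to zero at both cycle
    boundaries, so the implied linear velocity trend is subtracted before
    integrating to displacement.  ``axis=None`` selects the gravity-removed
    dominant horizontal axis instead of a fixed one.
    """
    step_times = np.asarray(step_times, dtype=float)
    if len(step_times) < 2:
        warnings.warn("fewer than one full gait cycle", stacklevel=2)
        return np.empty(0)
    if axis is None:
        acc = _gravity_removed_horizontal(recording)
    else:
        acc = recording.accel[:, _AXIS_INDEX[axis]]
    t = recording.time
    out = []
    for t0, t1 in zip(step_times, step_times[1:]):
        sel = (t >= t0) & (t <= t1)
        if sel.sum() < 3:
            out.append(0.0)
            continue
        tt = t[sel]
        aa = acc[sel]
        v = np.concatenate(
            [[0.0], np.cumsum(0.5 * (aa[1:] + aa[:-1]) * np.diff(tt))]
        )
        # ZUPT: v(t0)=v(t1)=0; subtract the linear drift ramp
        span = tt[-1] - tt[0]
        if span > 0:
            v = v - (tt - tt[0]) / span * v[-1]
        disp = np.sum(0.5 * (v[1:] + v[:-1]) * np.diff(tt))
        out.append(abs(float(disp)))
    return np.asarray(out)


def merge_prediction_intervals(
    track: FogPredictionTrack, gap_tolerance: int = 1
) -> list[tuple[float, float]]:
    """Merge consecutive FOG-labelled windows into freeze intervals.

    Runs of FOG windows separated by at most ``gap_tolerance`` non-FOG
    windows are joined.  Interval bounds are the end times of the first and
    last FOG window of the run.
    """
    times = np.asarray(track.window_end_times)
    fog = np.asarray(track.labels_pred, dtype=bool)
    intervals: list[tuple[float, float]] = []
    start = last = None
    gap = 0
    for t, f in zip(times, fog):
        if f:
            if start is None:
                start = t
            last = t
            gap = 0
        elif start is not None:
            gap += 1
            if gap > gap_tolerance:
                intervals.append((float(start), float(last)))
                start = last = None
                gap = 0
    if start is not None:
        intervals.append((float(start), float(last)))
    return intervals


def freeze_metrics(
    source: GaitEventLog | FogPredictionTrack | list[tuple[float, float]],
    completion_window: tuple[float, float],
    gap_tolerance: int = 1,
) -> tuple[int, float, float]:
    """(freeze_count, cumulative freeze time s, % of completion time).

    Accepts an observer event log, a detector prediction track (merged into
    intervals first), or explicit intervals.  Intervals extending beyond the
    completion window are clipped with a warning.
    """
    w0, w1 = completion_window
    if w1 <= w0:
        raise ValidationError("completion window must have positive length")
    if isinstance(source, GaitEventLog):
        intervals = source.freeze_intervals()
    elif isinstance(source, FogPredictionTrack):
        intervals = merge_prediction_intervals(source, gap_tolerance)
    else:
        intervals = list(source)
    clipped = []
    for s, e in intervals:
        if s < w0 or e > w1:
            warnings.warn(
                f"freeze interval ({s:g}, {e:g}) clipped to completion "
                "window",
                stacklevel=2,
            )
        s, e = max(s, w0), min(e, w1)
        if e > s:
            clipped.append((s, e))
    total = float(sum(e - s for s, e in clipped))
    completion = w1 - w0
    return len(clipped), total, 100.0 * total / completion


def observer_cv(values_by_observer: np.ndarray) -> float:
    """Percentage coefficient of variation between observer scores.

    ``values_by_observer`` is (n_observers,) for one trial or
    (n_trials, n_observers); per trial %CV = 100 * sample SD / mean,
    averaged across trials.
    """
    arr = np.atleast_2d(np.asarray(values_by_observer, dtype=float))
    if arr.shape[1] < 2:
        raise ValidationError("observer %CV requires >= 2 observers")
    means = arr.mean(axis=1)
    if np.any(means == 0):
        raise ValidationError("observer %CV undefined for zero-mean scores")
    cvs = 100.0 * arr.std(axis=1, ddof=1) / means
    return float(cvs.mean())


def summarize(
    log: GaitEventLog,
    completion_window: tuple[float, float] | None = None,
    recording: ImuRecording | None = None,
    stride_axis: str | None = "x",
) -> GaitSummary:
    """Full gait summary for one circuit from an event log (plus optional
    IMU recording for stride lengths)."""
    if completion_window is None:
        completion_window = log.segment_window()
        if completion_window is None:
            raise ValidationError(
                "no completion window: log has no segment markers"
            )
    w0, w1 = completion_window
    completion = w1 - w0
    strikes = log.strike_times()
    strikes = strikes[(strikes >= w0) & (strikes <= w1)]
    try:
        sym = symmetry_index(log)
    except ValidationError:
        sym = None
    n_freeze, t_freeze, pct = freeze_metrics(log, completion_window)
    strides = np.empty(0)
    if recording is not None:
        left = log.strike_times("left")
        strides = stride_length(recording, left, axis=stride_axis)
    return GaitSummary(
        step_count=len(strikes),
        step_frequency=step_frequency(strikes, completion),
        symmetry_index=sym,
        stride_lengths=strides,
        mean_stride_length=float(strides.mean()) if len(strides) else None,
        freeze_count=n_freeze,
        cumulative_freeze_time=t_freeze,
        freeze_time_fraction=pct,
        completion_time=completion,
    )
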