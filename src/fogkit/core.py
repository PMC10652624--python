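"""Shared domain types: IMU recordings, per-sample FOG labels, gait event logs.

A recording holds one leg-worn sensor's tri-axial accelerometer (m/s^2) and,
optionally, gyroscope (deg/s) streams, with per-sample freezing-of-gait (FOG)
labels when annotation exists.  An event log holds the timestamped gait events
an observer (or a detector) produced: left/right foot strikes, freeze
start/end, and segment boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class FogLabel(enum.IntEnum):
    """Per-sample annotation codes (Daphnet convention: 0/1/2)."""

    UNANNOTATED = 0
    NO_FOG = 1
    FOG = 2


class EventType(str, enum.Enum):
    STRIKE_LEFT = "strike_left"
    STRIKE_RIGHT = "strike_right"
    FREEZE_START = "freeze_start"
    FREEZE_END = "freeze_end"
    SEGMENT_START = "segment_start"
    SEGMENT_END = "segment_end"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class ImuRecording:
    """Timestamped 6-DoF samples for one leg sensor.

    Attributes
    ----------
    subject_id, segment_id : str
        Identity of the wearer and of the recording segment.
    sampling_rate : float
        Nominal sampling rate in Hz; the median sample interval must agree
        with ``1/sampling_rate`` to within 10%.
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Acceleration (X, Y, Z) in m/s^2.
    gyro : ndarray, shape (n, 3), optional
        Angular velocity in deg/s.
    labels : ndarray of int8, shape (n,), optional
        Per-sample :class:`FogLabel` codes.
    """

    subject_id: str
    segment_id: str
    sampling_rate: float
    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray | None = None
    labels: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n = self.time.shape[0]
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if n >= 2:
            dt = np.diff(self.time)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                # bad[0] indexes the diff; the offending sample is the next
                # row, reported 1-based
                raise ValidationError(
                    f"time not strictly increasing at row {int(bad[0]) + 2}"
                )
            nominal = 1.0 / self.sampling_rate
            if abs(np.median(dt) - nominal) > 0.1 * nominal:
                raise ValidationError(
                    "median sampling interval disagrees with sampling_rate "
                    f"by more than 10% (median dt={np.median(dt):.6g} s, "
                    f"nominal {nominal:.6g} s)"
                )
        if self.accel.shape != (n, 3):
            raise ValidationError(f"accel must have shape ({n}, 3)")
        if self.gyro is not None and self.gyro.shape != (n, 3):
            raise ValidationError(f"gyro must have shape ({n}, 3)")
        if self.labels is not None and self.labels.shape != (n,):
            raise ValidationError(f"labels must have shape ({n},)")

    def __len__(self) -> int:
        return int(self.time.shape[0])

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (one trailing interval
        included so that n samples at rate fs have duration n/fs)."""
        if len(self) == 0:
            return 0.0
        return float(self.time[-1] - self.time[0] + 1.0 / self.sampling_rate)


_STRIKES = (EventType.STRIKE_LEFT, EventType.STRIKE_RIGHT)


@dataclass
class GaitEvent:
    time: float
    event_type: EventType
    side: str | None = None  # "left"/"right" for strikes, else None


@dataclass
class GaitEventLog:
    """Ordered, validated sequence of timestamped gait events."""

    events: list[GaitEvent] = field(default_factory=list)
    observer_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("event times must be non-decreasing")
        open_freeze: float | None = None
        seg_open = 0
        for e in self.events:
            if e.event_type is EventType.FREEZE_START:
                if open_freeze is not None:
                    raise ValidationError(
                        f"freeze_start at t={e.time:g} s before previous "
                        "freeze ended"
                    )
                open_freeze = e.time
            elif e.event_type is EventType.FREEZE_END:
                if open_freeze is None:
                    raise ValidationError(
                        f"freeze_end at t={e.time:g} s without matching "
                        "freeze_start"
                    )
                open_freeze = None
            elif e.event_type is EventType.SEGMENT_START:
                seg_open += 1
            elif e.event_type is EventType.SEGMENT_END:
                seg_open -= 1
                if seg_open < 0:
                    raise ValidationError(
                        f"segment_end at t={e.time:g} s precedes segment_start"
                    )
        if open_freeze is not None:
            raise ValidationError(
                f"freeze_start at t={open_freeze:g} s never closed"
            )

    def __len__(self) -> int:
        return len(self.events)

    def strike_times(self, side: str | None = None) -> np.ndarray:
        """Foot-strike times; ``side`` restricts to 'left' or 'right'."""
        if side is None:
            sel = [e.time for e in self.events if e.event_type in _STRIKES]
        else:
            want = (
                EventType.STRIKE_LEFT if side == "left"
                else EventType.STRIKE_RIGHT
            )
            sel = [e.time for e in self.events if e.event_type is want]
        return np.asarray(sel, dtype=float)

    def freeze_intervals(self) -> list[tuple[float, float]]:
        out: list[tuple[float, float]] = []
        start: float | None = None
        for e in self.events:
            if e.event_type is EventType.FREEZE_START:
                start = e.time
            elif e.event_type is EventType.FREEZE_END:
                assert start is not None  # guaranteed by validate()
                out.append((start, e.time))
                start = None
        return out

    def segment_window(self) -> tuple[float, float] | None:
        """(start, end) of the first segment pair, if marked."""
        start = end = None
        for e in self.events:
            if e.event_type is EventType.SEGMENT_START and start is None:
                start = e.time
            elif e.event_type is EventType.SEGMENT_END and end is None:
                end = e.time
        if start is None or end is None:
            return None
        return (start, end)
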