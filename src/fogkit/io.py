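"""Readers and writers for recordings, window features, and gait event logs.

Two recording dialects are supported:

* ``native_csv`` — the package's own columnar text format:
  comment lines carrying metadata (``# key: value``), then a header row
  ``time_s,ax,ay,az,gx,gy,gz,label`` and one row per sample.
* ``daphnet`` — whitespace-separated annotated lower-leg accelerometer text:
  integer milliseconds, acceleration channels in milli-g, and a trailing
  annotation column coded 0 (unannotated), 1 (no freeze), 2 (freeze).  Only
  the ankle (shank) acceleration channels — the first three — are retained,
  converted to m/s^2.

All readers validate and reject malformed input (citing the offending row)
rather than silently repairing it; every writer round-trips through its
paired reader with no loss beyond the stated float precision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EventType,
    FogLabel,
    GaitEvent,
    GaitEventLog,
    ImuRecording,
    ValidationError,
)
from .features import FeatureSet

#: milli-g -> m/s^2 conversion used for Daphnet-style acceleration columns
MILLI_G = 9.80665e-3

_LABEL_NAMES = {
    FogLabel.UNANNOTATED: "unannotated",
    FogLabel.NO_FOG: "no_fog",
    FogLabel.FOG: "fog",
}
_LABEL_CODES = {v: k for k, v in _LABEL_NAMES.items()}

_FLOAT_FMT = "%.17g"  # lossless for float64


def write_recording(recording: ImuRecording, path: str | Path) -> None:
    """Write a recording in the native CSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {recording.subject_id}\n")
        fh.write(f"# segment_id: {recording.segment_id}\n")
        fh.write(f"# sampling_rate: {recording.sampling_rate!r}\n")
        if recording.seed is not None:
            fh.write(f"# seed: {recording.seed}\n")
        cols = {"time_s": recording.time}
        for i, ax in enumerate(("ax", "ay", "az")):
            cols[ax] = recording.accel[:, i]
        if recording.gyro is not None:
            for i, gx in enumerate(("gx", "gy", "gz")):
                cols[gx] = recording.gyro[:, i]
        frame = pd.DataFrame(cols)
        if recording.labels is not None:
            frame["label"] = [
                _LABEL_NAMES[FogLabel(int(v))] for v in recording.labels
            ]
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_native(path: Path) -> ImuRecording:
    meta: dict[str, str] = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    frame = pd.read_csv(body, float_precision="round_trip")
    if "time_s" not in frame.columns:
        raise ValidationError(f"{path}: missing time_s column")
    for col in ("ax", "ay", "az"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column {col}")
    gyro = None
    if {"gx", "gy", "gz"}.issubset(frame.columns):
        gyro = frame[["gx", "gy", "gz"]].to_numpy(float)
    labels = None
    if "label" in frame.columns:
        try:
            labels = np.array(
                [int(_LABEL_CODES[str(v)]) for v in frame["label"]],
                dtype=np.int8,
            )
        except KeyError as exc:
            raise ValidationError(
                f"{path}: unknown label {exc.args[0]!r}"
            ) from None
    if "sampling_rate" not in meta:
        raise ValidationError(f"{path}: missing '# sampling_rate:' header")
    seed = int(meta["seed"]) if "seed" in meta else None
    return ImuRecording(
        subject_id=meta.get("subject_id", path.stem),
        segment_id=meta.get("segment_id", ""),
        sampling_rate=float(meta["sampling_rate"]),
        time=frame["time_s"].to_numpy(float),
        accel=frame[["ax", "ay", "az"]].to_numpy(float),
        gyro=gyro,
        labels=labels,
        seed=seed,
    )


def _read_daphnet(path: Path, sampling_rate: float | None) -> ImuRecording:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValidationError(
                    f"{path}: malformed row at line {lineno} "
                    f"({len(parts)} fields, expected >= 5)"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ValidationError(
                    f"{path}: malformed row at line {lineno}: "
                    f"non-numeric field"
                ) from None
    if not rows:
        raise ValidationError(f"{path}: empty file")
    arr = np.asarray(rows)
    time = arr[:, 0] / 1000.0  # integer ms -> s
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: time not strictly increasing at row {int(bad[0]) + 2}"
        )
    # first three channels after the timestamp: ankle/shank acceleration
    accel = arr[:, 1:4] * MILLI_G
    labels = arr[:, -1].astype(np.int8)
    if not np.isin(labels, [0, 1, 2]).all():
        raise ValidationError(f"{path}: annotation codes must be 0/1/2")
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return ImuRecording(
        subject_id=path.stem,
        segment_id="daphnet",
        sampling_rate=sampling_rate,
        time=time,
        accel=accel,
        gyro=None,
        labels=labels,
    )


def read_recording(
    path: str | Path,
    format: str = "native_csv",
    sampling_rate: float | None = None,
) -> ImuRecording:
    """Read a recording in the ``native_csv`` or ``daphnet`` dialect.

    For the Daphnet dialect, ``sampling_rate`` may be given explicitly;
    otherwise it is inferred from the median timestamp interval.  Rows
    annotated 0 are retained but flagged unannotated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native_csv":
        return _read_native(path)
    if format == "daphnet":
        return _read_daphnet(path, sampling_rate)
    raise ValidationError(f"unknown recording format {format!r}")


def write_features(features: FeatureSet, path: str | Path) -> None:
    """Write window features as columnar text (>= 12 significant digits)."""
    if len(features) == 0:
        raise ValidationError("no features to write")
    if features.matrix.shape[1] != len(features.columns):
        raise ValidationError("heterogeneous feature vectors")
    frame = pd.DataFrame(features.matrix, columns=list(features.columns))
    frame.insert(0, "window_end_time", features.times)
    frame["label"] = [
        _LABEL_NAMES[FogLabel(int(v))] for v in features.labels
    ]
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {features.subject_id}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_features(path: str | Path) -> FeatureSet:
    """Read a feature file written by :func:`write_features`."""
    path = Path(path)
    meta: dict[str, str] = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    frame = pd.read_csv(body, float_precision="round_trip")
    cols = [c for c in frame.columns if c not in ("window_end_time", "label")]
    labels = np.array(
        [int(_LABEL_CODES[str(v)]) for v in frame["label"]], dtype=np.int8
    )
    return FeatureSet(
        times=frame["window_end_time"].to_numpy(float),
        matrix=frame[cols].to_numpy(float),
        labels=labels,
        subject_id=meta.get("subject_id", path.stem),
        columns=tuple(cols),
    )


_EVENT_TYPES = {e.value: e for e in EventType}


def write_event_log(log: GaitEventLog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# observer_id: {log.observer_id}\n")
        fh.write("time_s,event_type,side\n")
        for e in log.events:
            fh.write(
                f"{e.time!r},{e.event_type.value},{e.side or ''}\n"
            )


def read_event_log(path: str | Path) -> GaitEventLog:
    """Read and validate an event-log CSV (time_s, event_type, side)."""
    path = Path(path)
    meta: dict[str, str] = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    frame = pd.read_csv(
        body, keep_default_na=False, float_precision="round_trip"
    )
    events = []
    for _, row in frame.iterrows():
        etype = str(row["event_type"])
        if etype not in _EVENT_TYPES:
            raise ValidationError(
                f"{path}: unknown event type {etype!r} "
                f"at t={row['time_s']}"
            )
        side = str(row.get("side", "")) or None
        events.append(
            GaitEvent(float(row["time_s"]), _EVENT_TYPES[etype], side)
        )
    return GaitEventLog(events=events, observer_id=meta.get("observer_id", ""))
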