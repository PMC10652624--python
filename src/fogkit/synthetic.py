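"""Synthetic lower-leg IMU gait generator with exact ground truth.

The generator produces labelled recordings with the statistical structure the
FOG-detection stack assumes, so the whole pipeline can be exercised without
any external dataset:

* walking bouts — periodic shank angular-velocity pulses at the step
  frequency, and acceleration whose power is dominated by the locomotor
  fundamental (step frequency in Hz) plus two harmonics with geometrically
  decaying amplitude (decay 0.25, keeping >= 90% of in-band power below
  3 Hz at the default 100 steps/min);
* FOG episodes from a renewal process — onsets Poisson at
  ``fog_episode_rate``, durations log-normal with the configured mean/sd;
  trembling episodes oscillate at ``freeze_tremble_frequency`` (3–8 Hz),
  akinetic episodes are near-motionless; both are labelled FOG;
* additive white Gaussian sensor noise.

A second constructor, :func:`generate_trajectory`, builds a forward foot
displacement profile with *known* per-cycle stride lengths (minimum-jerk
swing between stance phases) and differentiates it analytically, so that
drift-corrected double integration can be validated against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    EventType,
    FogLabel,
    GaitEvent,
    GaitEventLog,
    ImuRecording,
    ValidationError,
)


class ConfigurationError(ValidationError):
    """A SyntheticConfig invariant was violated."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic gait model.

    Units: rates in Hz or per-minute as named, amplitudes in m/s^2,
    angular rate in deg/s, durations in seconds.
    """

    sampling_rate: float = 100.0
    duration: float = 600.0
    step_frequency: float = 100.0  # steps/min
    stride_length_mean: float = 1.2
    stride_length_sd: float = 0.1
    walk_band_amplitude: float = 2.0
    freeze_tremble_frequency: float = 5.0
    freeze_tremble_amplitude: float = 1.5
    fog_episode_rate: float = 1.0  # episodes/min
    fog_duration_mean: float = 8.0
    fog_duration_sd: float = 4.0
    fog_mode_mix: float = 0.7  # fraction of trembling (vs akinetic) episodes
    noise_sd: float = 0.15
    gyro_peak_amplitude: float = 200.0
    gravity_offset: float = 0.0  # constant m/s^2 added to the z axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 16.0:
            raise ConfigurationError(
                "sampling_rate must exceed 16 Hz (twice the 8 Hz freeze-band "
                "upper edge)"
            )
        if not (3.0 <= self.freeze_tremble_frequency <= 8.0):
            raise ConfigurationError(
                "freeze_tremble_frequency must lie in [3, 8] Hz"
            )
        f_step = self.step_frequency / 60.0
        if self.step_frequency > 0 and not (0.5 <= f_step <= 3.0):
            raise ConfigurationError(
                "step_frequency must place the locomotor fundamental "
                f"in [0.5, 3] Hz (got {f_step:g} Hz)"
            )
        if not (0.0 <= self.fog_mode_mix <= 1.0):
            raise ConfigurationError("fog_mode_mix must lie in [0, 1]")
        for name in (
            "duration",
            "stride_length_sd",
            "walk_band_amplitude",
            "freeze_tremble_amplitude",
            "fog_episode_rate",
            "fog_duration_mean",
            "fog_duration_sd",
            "noise_sd",
            "gyro_peak_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-sample and per-event truth for a synthetic recording."""

    fog_mask: np.ndarray  # bool per sample
    step_times: dict[str, np.ndarray]  # side -> strictly increasing times
    stride_lengths: np.ndarray  # m per gait cycle
    episode_list: list[tuple[float, float, str]] = field(default_factory=list)

    def all_step_times(self) -> np.ndarray:
        return np.sort(
            np.concatenate([self.step_times["left"], self.step_times["right"]])
        )


#: amplitude decay between consecutive walking harmonics
_HARMONIC_DECAY = 0.25
#: width (s) of a gyro step pulse (Gaussian sigma)
_PULSE_SIGMA = 0.05


def _draw_episodes(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[float, float, str]]:
    """FOG episodes: Poisson onsets, log-normal durations, no overlap."""
    if config.fog_episode_rate == 0 or config.duration == 0:
        return []
    rate = config.fog_episode_rate / 60.0  # per second
    n = rng.poisson(rate * config.duration)
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(0.0, config.duration, size=n))
    m, s = config.fog_duration_mean, config.fog_duration_sd
    if m <= 0:
        return []
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    durations = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    modes = np.where(
        rng.uniform(size=n) < config.fog_mode_mix, "trembling", "akinetic"
    )
    episodes: list[tuple[float, float, str]] = []
    cursor = 0.0
    for start, dur, mode in zip(onsets, durations, modes):
        start = max(start, cursor + 1.0)  # >= 1 s walking between episodes
        end = min(start + dur, config.duration)
        if end - start < 0.5 or start >= config.duration:
            continue
        episodes.append((float(start), float(end), str(mode)))
        cursor = end
    return episodes


def _walking_accel(
    t: np.ndarray, f_step: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Tri-axial locomotor acceleration: fundamental + 2 decaying harmonics."""
    acc = np.zeros((t.shape[0], 3))
    if amplitude == 0 or f_step == 0:
        return acc
    axis_scale = np.array([1.0, 0.6, 0.4])
    for ax in range(3):
        for h in range(3):
            phase = rng.uniform(0, 2 * np.pi)
            acc[:, ax] += (
                amplitude
                * axis_scale[ax]
                * _HARMONIC_DECAY**h
                * np.sin(2 * np.pi * f_step * (h + 1) * t + phase)
            )
    return acc


def generate_recording(
    config: SyntheticConfig,
) -> tuple[ImuRecording, GroundTruth]:
    """Synthesize a labelled walking/FOG recording with exact ground truth.

    The signal alternates walking bouts with FOG episodes drawn from a
    renewal process; ``GroundTruth.fog_mask`` is true exactly inside the
    episode intervals, and step times never fall inside an episode.
    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    f_step = config.step_frequency / 60.0

    episodes = _draw_episodes(config, rng)
    fog_mask = np.zeros(n, dtype=bool)
    for start, end, _mode in episodes:
        fog_mask[(t >= start) & (t < end)] = True

    accel = _walking_accel(t, f_step, config.walk_band_amplitude, rng)
    # FOG episodes replace the locomotor signal
    for start, end, mode in episodes:
        seg = (t >= start) & (t < end)
        accel[seg] = 0.0
        if mode == "trembling" and config.freeze_tremble_amplitude > 0:
            tremble_axis_scale = np.array([1.0, 0.8, 0.5])
            for ax in range(3):
                phase = rng.uniform(0, 2 * np.pi)
                accel[seg, ax] = (
                    config.freeze_tremble_amplitude
                    * tremble_axis_scale[ax]
                    * np.sin(
                        2 * np.pi * config.freeze_tremble_frequency * t[seg]
                        + phase
                    )
                )

    # step times: regular grid at the step frequency, outside episodes,
    # alternating sides
    step_times_all: list[float] = []
    if f_step > 0 and config.walk_band_amplitude > 0:
        grid = np.arange(0.5 / f_step, config.duration, 1.0 / f_step)
        for st in grid:
            if not any(s <= st < e for s, e, _ in episodes):
                step_times_all.append(float(st))
    left = np.asarray(step_times_all[0::2])
    right = np.asarray(step_times_all[1::2])

    gyro = np.zeros((n, 3))
    if config.gyro_peak_amplitude > 0:
        for st in step_times_all:
            lo = max(0, int((st - 4 * _PULSE_SIGMA) * fs))
            hi = min(n, int((st + 4 * _PULSE_SIGMA) * fs) + 1)
            gyro[lo:hi, 1] += config.gyro_peak_amplitude * np.exp(
                -0.5 * ((t[lo:hi] - st) / _PULSE_SIGMA) ** 2
            )

    if config.noise_sd > 0:
        accel += rng.normal(0.0, config.noise_sd, size=accel.shape)
        gyro += rng.normal(0.0, config.noise_sd * 10.0, size=gyro.shape)
    if config.gravity_offset:
        accel[:, 2] += config.gravity_offset

    labels = np.where(fog_mask, int(FogLabel.FOG), int(FogLabel.NO_FOG))
    rec = ImuRecording(
        subject_id=f"synth-{config.seed}",
        segment_id="synthetic",
        sampling_rate=fs,
        time=t,
        accel=accel,
        gyro=gyro,
        labels=labels.astype(np.int8),
        seed=config.seed,
    )
    truth = GroundTruth(
        fog_mask=fog_mask,
        step_times={"left": left, "right": right},
        stride_lengths=np.full(
            max(len(step_times_all) // 2, 0), config.stride_length_mean
        ),
        episode_list=episodes,
    )
    return rec, truth


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0,1]: zero vel/acc at both ends."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _min_jerk_accel(tau: np.ndarray) -> np.ndarray:
    """Second derivative of the minimum-jerk profile (per unit time^2)."""
    return 60 * tau - 180 * tau**2 + 120 * tau**3


def generate_trajectory(
    config: SyntheticConfig,
    accel_bias: float = 0.0,
    n_cycles: int | None = None,
) -> tuple[ImuRecording, GroundTruth]:
    """Forward foot kinematics with exactly known per-cycle stride lengths.

    Each gait cycle (two steps, one per side) lasts ``2 / f_step`` seconds:
    the instrumented foot is stationary during the first half (stance) and
    translates forward by the cycle's stride length during the second half
    along a minimum-jerk profile, which has zero velocity and acceleration
    at both ends.  The x-axis accelerometer reads the analytic second
    derivative, so exact double integration recovers the strides; a constant
    ``accel_bias`` can be added to exercise drift correction — the ground
    truth is kinematic and does not change.
    """
    if config.stride_length_mean <= 0:
        raise ConfigurationError("stride_length_mean must be positive")
    f_step = config.step_frequency / 60.0
    if f_step <= 0:
        raise ConfigurationError("step_frequency must be positive")
    t_cycle = 2.0 / f_step
    if n_cycles is None:
        n_cycles = int(config.duration // t_cycle)
    if n_cycles < 1:
        raise ConfigurationError("no gait cycles fit in the duration")
    config = replace(config, duration=n_cycles * t_cycle)

    rng = np.random.default_rng(config.seed)
    strides = config.stride_length_mean + config.stride_length_sd * rng.normal(
        size=n_cycles
    )
    strides = np.maximum(strides, 0.1 * config.stride_length_mean)

    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    accel_x = np.zeros(n)
    t_swing = t_cycle / 2.0
    for c in range(n_cycles):
        sw0 = c * t_cycle + t_cycle / 2.0
        seg = (t >= sw0) & (t < sw0 + t_swing)
        tau = (t[seg] - sw0) / t_swing
        accel_x[seg] = strides[c] / t_swing**2 * _min_jerk_accel(tau)
    # instrumented-foot strikes: stance onset at t=0, then the end of each
    # swing; cycle c runs strike c -> strike c+1 with displacement strides[c]
    strikes_arr = np.concatenate(
        [[0.0], (np.arange(n_cycles) + 1) * t_cycle]
    )
    strikes_arr = np.minimum(strikes_arr, t[-1])

    accel = np.zeros((n, 3))
    accel[:, 0] = accel_x + accel_bias
    if config.noise_sd > 0:
        accel += rng.normal(0.0, config.noise_sd, size=accel.shape)

    gyro = np.zeros((n, 3))
    for st in strikes_arr:
        lo = max(0, int((st - 4 * _PULSE_SIGMA) * fs))
        hi = min(n, int((st + 4 * _PULSE_SIGMA) * fs) + 1)
        gyro[lo:hi, 1] += config.gyro_peak_amplitude * np.exp(
            -0.5 * ((t[lo:hi] - st) / _PULSE_SIGMA) ** 2
        )

    rec = ImuRecording(
        subject_id=f"synth-traj-{config.seed}",
        segment_id="trajectory",
        sampling_rate=fs,
        time=t,
        accel=accel,
        gyro=gyro,
        labels=np.full(n, int(FogLabel.NO_FOG), dtype=np.int8),
        seed=config.seed,
    )
    truth = GroundTruth(
        fog_mask=np.zeros(n, dtype=bool),
        step_times={"left": strikes_arr, "right": np.empty(0)},
        stride_lengths=strides,
        episode_list=[],
    )
    return rec, truth


def generate_event_log(
    config: SyntheticConfig,
    truth: GroundTruth,
    jitter_sd: float = 0.0,
    observer_id: str = "synthetic",
    jitter_seed: int | None = None,
) -> GaitEventLog:
    """Emit the ground truth as an observer-style gait event log.

    ``jitter_sd`` (seconds, default 0) adds Gaussian latency to every event
    to emulate human keystroke timing; jitter is seeded by ``config.seed``
    (or ``jitter_seed``, e.g. one per simulated observer) so logs are
    reproducible.
    """
    if jitter_seed is None:
        jitter_seed = config.seed + 1
    rng = np.random.default_rng(jitter_seed)

    def jitter(x: float) -> float:
        if jitter_sd > 0:
            return float(x + rng.normal(0.0, jitter_sd))
        return float(x)

    events: list[GaitEvent] = []
    events.append(GaitEvent(0.0, EventType.SEGMENT_START))
    for side in ("left", "right"):
        etype = (
            EventType.STRIKE_LEFT if side == "left" else EventType.STRIKE_RIGHT
        )
        for st in truth.step_times[side]:
            events.append(GaitEvent(jitter(float(st)), etype, side))
    for start, end, _mode in truth.episode_list:
        s = jitter(start)
        e = max(jitter(end), s + 1e-6)
        events.append(GaitEvent(s, EventType.FREEZE_START))
        events.append(GaitEvent(e, EventType.FREEZE_END))
    events.append(GaitEvent(float(config.duration), EventType.SEGMENT_END))
    events.sort(key=lambda ev: (ev.time, ev.event_type is EventType.FREEZE_END))
    return GaitEventLog(events=events, observer_id=observer_id)
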