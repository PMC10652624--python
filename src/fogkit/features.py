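"""Spectral and time-domain window features for FOG detection.

The detector works on fixed-length windows (default 256 samples, about 2.5 s
at 100 Hz) of each accelerometer axis.  Six features are computed per axis:

* ``freeze_index`` — ratio of spectral power in the freeze band (3–8 Hz,
  trembling during a freezing episode) to power in the walking band
  (0.5–3 Hz, locomotor oscillation).  The ratio alone is unbounded when the
  wearer stands still, so the denominator is floored at ``epsilon_power``.
* ``band_power`` — total power over 0.5–8 Hz; disambiguates stillness (low
  power) from trembling (high freeze index *and* high power).
* ``variance``, ``l1_norm``, ``l2_norm`` — time-domain statistics of the raw
  window (variance with divisor N; norms on the un-centred samples).
* ``entropy`` — Shannon entropy (nats) of the periodogram normalised over the
  0.5–8 Hz bins; low for a single tone, high for broadband noise.

Two computation paths exist and are equivalent to floating-point tolerance:
a batch path (windowed FFT over a whole recording) and a streaming path that
maintains the tracked DFT bins with a per-sample sliding-DFT recurrence, so
an embedded device can update features in O(number of tracked bins) per
sample instead of an FFT per window.

Periodogram convention: rectangular window, one-sided spectrum with power
``P_k = |X_k|^2 / N^2`` at DC and Nyquist and ``2 |X_k|^2 / N^2`` elsewhere,
so the full-spectrum power sums to the window mean square (Parseval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FogLabel, ImuRecording, ValidationError

FEATURE_NAMES = (
    "freeze_index",
    "band_power",
    "variance",
    "l1_norm",
    "l2_norm",
    "entropy",
)
AXES = ("x", "y", "z")

#: Column names of the flattened 18-dimensional feature vector.
FEATURE_COLUMNS = tuple(
    f"a{ax}_{name}" for ax in AXES for name in FEATURE_NAMES
)


@dataclass(frozen=True)
class BandDefinition:
    """Frequency bands and window geometry for feature extraction.

    ``walk_band`` and ``freeze_band`` partition ``total_band`` at 3 Hz.
    Band membership of a DFT bin is decided by its centre frequency
    ``k * fs / N`` with half-open intervals ``[f1, f2)``, so the 3 Hz edge
    belongs to the freeze band and the two bands never double-count; the
    upper edge of the total band is inclusive.
    """

    walk_band: tuple[float, float] = (0.5, 3.0)
    freeze_band: tuple[float, float] = (3.0, 8.0)
    total_band: tuple[float, float] = (0.5, 8.0)
    window_length: int = 256
    epsilon_power: float = 1e-8

    def __post_init__(self) -> None:
        n = self.window_length
        if n < 2 or (n & (n - 1)) != 0:
            raise ValidationError("window_length must be a power of two")
        if not (
            self.walk_band[0] == self.total_band[0]
            and self.walk_band[1] == self.freeze_band[0]
            and self.freeze_band[1] == self.total_band[1]
        ):
            raise ValidationError(
                "walk and freeze bands must partition the total band"
            )
        if self.epsilon_power <= 0:
            raise ValidationError("epsilon_power must be positive")

    def band_bins(
        self,
        fs: float,
        band: tuple[float, float],
        upper_inclusive: bool = False,
    ) -> np.ndarray:
        """Indices of one-sided DFT bins whose centre lies in the band."""
        f1, f2 = band
        if f2 > fs / 2:
            raise ValidationError(
                f"band upper edge {f2:g} Hz exceeds Nyquist {fs / 2:g} Hz"
            )
        k = np.arange(self.window_length // 2 + 1)
        f = k * fs / self.window_length
        mask = (f >= f1) & ((f <= f2) if upper_inclusive else (f < f2))
        return k[mask]

    def tracked_bins(self, fs: float) -> np.ndarray:
        """Bins the streaming path must maintain: the total band, upper
        edge inclusive."""
        return self.band_bins(fs, self.total_band, upper_inclusive=True)


DEFAULT_BANDS = BandDefinition()


def periodogram(window: np.ndarray) -> np.ndarray:
    """One-sided rectangular-window periodogram; sums to mean square."""
    w = np.asarray(window, dtype=float)
    n = w.shape[-1]
    coef = np.fft.rfft(w)
    p = np.abs(coef) ** 2 / n**2
    # double the bins that fold (all but DC, and Nyquist when n is even)
    last = p.shape[-1] - 1 if n % 2 == 0 else p.shape[-1]
    p[..., 1:last] *= 2.0
    return p


def _check_window(window: np.ndarray, bands: BandDefinition) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    if w.shape[-1] != bands.window_length:
        raise ValidationError(
            f"window length {w.shape[-1]} != configured "
            f"{bands.window_length}"
        )
    return w


def band_power(
    window: np.ndarray,
    fs: float,
    band: tuple[float, float],
    bands: BandDefinition = DEFAULT_BANDS,
    upper_inclusive: bool = False,
) -> float:
    """Total periodogram power over the DFT bins inside ``band``."""
    w = _check_window(window, bands)
    bins = bands.band_bins(fs, band, upper_inclusive=upper_inclusive)
    return float(periodogram(w)[..., bins].sum(axis=-1))


def freeze_index(
    window: np.ndarray, fs: float, bands: BandDefinition = DEFAULT_BANDS
) -> float:
    """Freeze-band / walking-band power ratio with an epsilon floor.

    The floor caps — it does not hide — stillness: a still window gives a
    near-zero numerator and a floored denominator, hence a small ratio, and
    the separate band-power feature identifies the low-movement state.
    """
    w = _check_window(window, bands)
    p = periodogram(w)
    pf = p[..., bands.band_bins(fs, bands.freeze_band)].sum(axis=-1)
    pw = p[..., bands.band_bins(fs, bands.walk_band)].sum(axis=-1)
    return float(pf / np.maximum(pw, bands.epsilon_power))


def time_domain_features(window: np.ndarray) -> tuple[float, float, float]:
    """(variance, L1 norm, L2 norm) of the raw window.

    Variance uses divisor N (population form); the norms are taken on the
    samples as-is, without mean removal.
    """
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValidationError("empty window")
    mean = w.mean(axis=-1)
    var = (w * w).mean(axis=-1) - mean * mean
    return (
        float(var),
        float(np.abs(w).sum(axis=-1)),
        float(np.sqrt((w * w).sum(axis=-1))),
    )


def spectral_entropy(
    window: np.ndarray, fs: float, bands: BandDefinition = DEFAULT_BANDS
) -> float:
    """Shannon entropy (nats) of the periodogram over the total-band bins.

    A zero-power window returns the maximum ``ln(n_bins)`` by convention:
    a spectrum with no power is uninformative about frequency content.
    """
    w = _check_window(window, bands)
    p = periodogram(w)[..., bands.tracked_bins(fs)]
    return _entropy_from_powers(p)


def _entropy_from_powers(p: np.ndarray) -> float:
    total = p.sum(axis=-1)
    n_bins = p.shape[-1]
    if total <= 0:
        return float(np.log(n_bins))
    q = p / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log(q), 0.0)
    return float(-terms.sum(axis=-1))


def _features_from_spectrum(
    p_tracked: np.ndarray,
    tracked: np.ndarray,
    walk_bins: np.ndarray,
    freeze_bins: np.ndarray,
    var: float,
    l1: float,
    l2: float,
    epsilon_power: float,
) -> np.ndarray:
    """Assemble the 6-feature vector for one axis from tracked-bin powers."""
    lookup = {int(k): i for i, k in enumerate(tracked)}
    pw = p_tracked[[lookup[int(k)] for k in walk_bins]].sum()
    pf = p_tracked[[lookup[int(k)] for k in freeze_bins]].sum()
    fi = pf / max(pw, epsilon_power)
    bp = p_tracked.sum()
    ent = _entropy_from_powers(p_tracked)
    return np.array([fi, bp, var, l1, l2, ent])


# ---------------------------------------------------------------------------
# Streaming path: sliding DFT
# ---------------------------------------------------------------------------


class SlidingDFT:
    """Per-sample recursive update of a tracked set of DFT bins.

    For the window ``w_t = [x_{t-N+1}, ..., x_t]`` the tracked coefficient
    is ``X_k(t) = sum_n w_t[n] exp(-2*pi*i*k*n/N)`` — exactly the bin the
    FFT of the ordered window would give.  On each new sample the
    recurrence ``X_k <- (X_k - x_oldest + x_new) * exp(2*pi*i*k/N)`` is
    applied, costing O(tracked bins) per sample independent of N.

    Floating-point drift is bounded by recomputing the coefficients (and the
    running time-domain sums) directly from the buffered window every
    ``renorm_interval`` updates.  ``op_count`` tallies arithmetic operations
    so the constant-per-sample cost contract can be asserted without
    wall-clock timing.
    """

    def __init__(
        self,
        window_length: int,
        tracked_bins: np.ndarray,
        renorm_interval: int = 4096,
    ) -> None:
        self.n = int(window_length)
        self.bins = np.asarray(tracked_bins, dtype=int)
        self.twiddle = np.exp(2j * np.pi * self.bins / self.n)
        self.renorm_interval = int(renorm_interval)
        self.buffer = np.zeros(self.n)
        self.pos = 0
        self.count = 0
        self.coeffs = np.zeros(len(self.bins), dtype=complex)
        self.sum = 0.0
        self.sum_sq = 0.0
        self.sum_abs = 0.0
        self._since_renorm = 0
        self.op_count = 0
        self.renorm_op_count = 0

    @property
    def ready(self) -> bool:
        """True once a full window of samples has been seen."""
        return self.count >= self.n

    def update(self, x: float) -> None:
        old = self.buffer[self.pos]
        self.coeffs = (self.coeffs + (x - old)) * self.twiddle
        self.sum += x - old
        self.sum_sq += x * x - old * old
        self.sum_abs += abs(x) - abs(old)
        self.buffer[self.pos] = x
        self.pos = (self.pos + 1) % self.n
        self.count += 1
        # complex add + complex multiply per bin, plus the running sums
        self.op_count += 8 * len(self.bins) + 8
        self._since_renorm += 1
        if self._since_renorm >= self.renorm_interval:
            self.renormalize()

    def window(self) -> np.ndarray:
        """Current window in time order (oldest first)."""
        return np.concatenate(
            [self.buffer[self.pos:], self.buffer[: self.pos]]
        )

    def renormalize(self) -> None:
        """Recompute tracked coefficients and sums directly from the buffer."""
        w = self.window()
        self.coeffs = np.fft.rfft(w)[self.bins].astype(complex)
        self.sum = float(w.sum())
        self.sum_sq = float((w * w).sum())
        self.sum_abs = float(np.abs(w).sum())
        self._since_renorm = 0
        # amortised: an N log N recompute every renorm_interval samples
        self.renorm_op_count += int(
            5 * self.n * np.log2(self.n)
        ) + 3 * self.n

    def tracked_powers(self) -> np.ndarray:
        """One-sided periodogram powers of the tracked bins."""
        p = np.abs(self.coeffs) ** 2 / self.n**2
        fold = (self.bins > 0) & (self.bins < self.n // 2)
        return np.where(fold, 2.0 * p, p)


class StreamingFeatureExtractor:
    """Tri-axial streaming feature computation with one SlidingDFT per axis."""

    def __init__(
        self,
        fs: float,
        bands: BandDefinition = DEFAULT_BANDS,
        renorm_interval: int = 4096,
    ) -> None:
        self.fs = float(fs)
        self.bands = bands
        self.tracked = bands.tracked_bins(fs)
        self.walk_bins = bands.band_bins(fs, bands.walk_band)
        self.freeze_bins = bands.band_bins(fs, bands.freeze_band)
        self.sdfts = [
            SlidingDFT(bands.window_length, self.tracked, renorm_interval)
            for _ in AXES
        ]

    @property
    def ready(self) -> bool:
        return self.sdfts[0].ready

    def update(self, sample: np.ndarray) -> None:
        """Push one tri-axial acceleration sample (shape (3,))."""
        for s, x in zip(self.sdfts, sample):
            s.update(float(x))

    def features(self) -> np.ndarray:
        """Current 18-dim feature vector (requires :attr:`ready`)."""
        if not self.ready:
            raise ValidationError("feature window not yet warmed up")
        out = np.empty(len(FEATURE_COLUMNS))
        for i, s in enumerate(self.sdfts):
            n = s.n
            mean = s.sum / n
            var = s.sum_sq / n - mean * mean
            out[6 * i: 6 * i + 6] = _features_from_spectrum(
                s.tracked_powers(),
                self.tracked,
                self.walk_bins,
                self.freeze_bins,
                var,
                s.sum_abs,
                float(np.sqrt(max(s.sum_sq, 0.0))),
                self.bands.epsilon_power,
            )
        return out

    def op_counts(self) -> dict[str, float]:
        n_updates = max(self.sdfts[0].count, 1)
        per_sample = sum(s.op_count for s in self.sdfts) / n_updates
        amortised = sum(s.renorm_op_count for s in self.sdfts) / n_updates
        return {
            "n_samples": self.sdfts[0].count,
            "n_tracked_bins": len(self.tracked),
            "window_length": self.bands.window_length,
            "ops_per_sample": per_sample,
            "renorm_ops_per_sample_amortised": amortised,
        }


# ---------------------------------------------------------------------------
# Window feature containers and batch extraction
# ---------------------------------------------------------------------------


@dataclass
class WindowFeatureVector:
    """Features of one window: 18 values (3 axes x 6 features) + label."""

    window_end_time: float
    values: np.ndarray
    label: FogLabel = FogLabel.UNANNOTATED


@dataclass
class FeatureSet:
    """Column-oriented batch of per-window feature vectors."""

    times: np.ndarray
    matrix: np.ndarray  # shape (n_windows, 18), columns FEATURE_COLUMNS
    labels: np.ndarray  # FogLabel codes, shape (n_windows,)
    subject_id: str = ""
    columns: tuple[str, ...] = field(default=FEATURE_COLUMNS)

    def __len__(self) -> int:
        return int(self.times.shape[0])

    def __getitem__(self, i: int) -> WindowFeatureVector:
        return WindowFeatureVector(
            float(self.times[i]),
            self.matrix[i],
            FogLabel(int(self.labels[i])),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def window_label(labels: np.ndarray) -> FogLabel:
    """Majority per-sample label of a window; ties resolve toward FOG
    (conservative for a detector that must not miss freezes), then NO_FOG."""
    counts = np.bincount(labels, minlength=3)
    order = (FogLabel.FOG, FogLabel.NO_FOG, FogLabel.UNANNOTATED)
    best = max(order, key=lambda c: (counts[c], order[::-1].index(c)))
    return best


def extract_features(
    recording: ImuRecording,
    bands: BandDefinition = DEFAULT_BANDS,
    hop: int = 32,
    mode: str = "batch",
) -> FeatureSet:
    """Per-window features over a recording.

    Windows are ``bands.window_length`` samples long and advance by ``hop``
    samples; each window is stamped with the time of its last sample.  The
    batch mode computes all windows with a vectorised FFT; ``mode="stream"``
    pushes samples one at a time through the sliding-DFT path and emits the
    same windows (used for equivalence checks and by the realtime engine).
    """
    if hop < 1:
        raise ValidationError("hop must be >= 1")
    n = bands.window_length
    n_samples = len(recording)
    if n_samples < n:
        warnings.warn(
            "recording shorter than one window; no features extracted",
            stacklevel=2,
        )
        return FeatureSet(
            np.empty(0), np.empty((0, 18)), np.empty(0, dtype=np.int8),
            subject_id=recording.subject_id,
        )
    ends = np.arange(n - 1, n_samples, hop)
    fs = recording.sampling_rate

    if mode == "stream":
        ext = StreamingFeatureExtractor(fs, bands)
        want = set(ends.tolist())
        rows = []
        for i in range(n_samples):
            ext.update(recording.accel[i])
            if i in want:
                rows.append(ext.features())
        mat = np.vstack(rows)
    elif mode == "batch":
        from numpy.lib.stride_tricks import sliding_window_view

        tracked = bands.tracked_bins(fs)
        walk = bands.band_bins(fs, bands.walk_band)
        freeze = bands.band_bins(fs, bands.freeze_band)
        lookup = {int(k): i for i, k in enumerate(tracked)}
        wsel = [lookup[int(k)] for k in walk]
        fsel = [lookup[int(k)] for k in freeze]
        mat = np.empty((len(ends), 18))
        for ax in range(3):
            views = sliding_window_view(recording.accel[:, ax], n)[ends - (n - 1)]
            coef = np.fft.rfft(views, axis=-1)[:, tracked]
            p = np.abs(coef) ** 2 / n**2
            fold = (tracked > 0) & (tracked < n // 2)
            p = np.where(fold, 2.0 * p, p)
            pw = p[:, wsel].sum(axis=1)
            pf = p[:, fsel].sum(axis=1)
            fi = pf / np.maximum(pw, bands.epsilon_power)
            bp = p.sum(axis=1)
            mean = views.mean(axis=1)
            sum_sq = (views * views).sum(axis=1)
            var = sum_sq / n - mean * mean
            l1 = np.abs(views).sum(axis=1)
            l2 = np.sqrt(sum_sq)
            total = p.sum(axis=1, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(total > 0, p / np.where(total > 0, total, 1.0), 0)
                terms = np.where(q > 0, q * np.log(q), 0.0)
            ent = np.where(
                total[:, 0] > 0, -terms.sum(axis=1), np.log(p.shape[1])
            )
            mat[:, 6 * ax: 6 * ax + 6] = np.column_stack(
                [fi, bp, var, l1, l2, ent]
            )
    else:
        raise ValidationError(f"unknown extraction mode {mode!r}")

    if recording.labels is not None:
        labels = np.array(
            [
                int(window_label(recording.labels[e - n + 1: e + 1]))
                for e in ends
            ],
            dtype=np.int8,
        )
    else:
        labels = np.full(len(ends), int(FogLabel.UNANNOTATED), dtype=np.int8)
    return FeatureSet(
        recording.time[ends].copy(), mat, labels,
        subject_id=recording.subject_id,
    )
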