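"""Spectral feature layer: periodogram-oracle checks, Parseval, sliding-DFT
equivalence, and batch/streaming agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram as sp_periodogram

from fogkit import (
    DEFAULT_BANDS,
    BandDefinition,
    SlidingDFT,
    StreamingFeatureExtractor,
    SyntheticConfig,
    band_power,
    extract_features,
    freeze_index,
    generate_recording,
    spectral_entropy,
    time_domain_features,
)
from fogkit.core import ValidationError
from fogkit.features import FogLabel, periodogram, window_label

FS = 100.0
N = 256


def tone(freq, n=N, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


def oracle_band_power(window, fs, lo, hi, upper_inclusive=False):
    """Independent periodogram oracle (scipy, boxcar, spectrum scaling)."""
    f, p = sp_periodogram(window, fs=fs, window="boxcar", scaling="spectrum")
    sel = (f >= lo) & ((f <= hi) if upper_inclusive else (f < hi))
    return p[sel].sum()


class TestBandPower:
    def test_freeze_band_tone(self):
        """Unit 5 Hz sinusoid: ~0.5 power in the freeze band, almost none
        in the walking band."""
        w = tone(5.0)
        pf = band_power(w, FS, DEFAULT_BANDS.freeze_band)
        pw = band_power(w, FS, DEFAULT_BANDS.walk_band)
        assert pf == pytest.approx(0.5, rel=0.05)
        assert pw < 0.02
        assert pf == pytest.approx(
            oracle_band_power(w, FS, 3.0, 8.0), rel=1e-9
        )

    def test_zero_window(self):
        w = np.zeros(N)
        for band in (
            DEFAULT_BANDS.walk_band,
            DEFAULT_BANDS.freeze_band,
            DEFAULT_BANDS.total_band,
        ):
            assert band_power(w, FS, band) == 0.0

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=N)
        full = periodogram(w).sum()
        assert full == pytest.approx(np.mean(w**2), rel=1e-9)

    def test_band_edges_partition(self):
        """Half-open bins: walk + freeze power equals [0.5, 8) power."""
        rng = np.random.default_rng(1)
        w = rng.normal(size=N)
        pw = band_power(w, FS, DEFAULT_BANDS.walk_band)
        pf = band_power(w, FS, DEFAULT_BANDS.freeze_band)
        ptot = band_power(w, FS, DEFAULT_BANDS.total_band)
        assert pw + pf == pytest.approx(ptot, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValidationError, match="window length"):
            band_power(np.zeros(100), FS, (0.5, 3.0))
        with pytest.raises(ValidationError, match="Nyquist"):
            band_power(np.zeros(N), FS, (0.5, 60.0))


class TestFreezeIndex:
    def test_tones(self):
        assert freeze_index(tone(5.0), FS) > 10
        assert freeze_index(tone(1.5), FS) < 0.1

    def test_matches_oracle_ratio(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=N)
        expected = oracle_band_power(w, FS, 3, 8) / oracle_band_power(
            w, FS, 0.5, 3
        )
        assert freeze_index(w, FS) == pytest.approx(expected, rel=1e-9)

    def test_zero_window_guarded(self):
        assert freeze_index(np.zeros(N), FS) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        scale=st.floats(1e-3, 1e3),
        seed=st.integers(0, 1000),
    )
    def test_scale_invariance(self, scale, seed):
        """freeze_index(c*w) == freeze_index(w) above the epsilon guard."""
        rng = np.random.default_rng(seed)
        w = rng.normal(size=N)
        assert freeze_index(scale * w, FS) == pytest.approx(
            freeze_index(w, FS), rel=1e-6
        )


class TestTimeDomain:
    @pytest.mark.parametrize(
        "window,expected",
        [
            (np.array([1.0, -1.0, 1.0, -1.0]), (1.0, 4.0, 2.0)),
            (np.zeros(8), (0.0, 0.0, 0.0)),
            (np.full(16, 3.0), (0.0, 48.0, 12.0)),
        ],
    )
    def test_hand_values(self, window, expected):
        var, l1, l2 = time_domain_features(window)
        assert var == pytest.approx(expected[0], abs=1e-12)
        assert l1 == pytest.approx(expected[1])
        assert l2 == pytest.approx(expected[2])


class TestSpectralEntropy:
    def test_single_tone_low(self):
        """A tone concentrates spectral mass in one or two bins: near-zero
        entropy on-bin; below ln(2) plus a leakage allowance off-bin."""
        on_bin = tone(13 * FS / N)  # exactly bin 13
        assert spectral_entropy(on_bin, FS) <= 0.1
        # 5 Hz falls between bins 12 and 13; leakage splits the power
        assert spectral_entropy(tone(5.0), FS) <= np.log(2) + 0.05

    def test_zero_window_max(self):
        n_bins = len(DEFAULT_BANDS.tracked_bins(FS))
        assert spectral_entropy(np.zeros(N), FS) == np.log(n_bins)

    def test_white_noise_matches_oracle(self):
        """Frozen oracle value for a seeded white-noise window: Shannon
        entropy of the scipy periodogram normalised over the in-band bins."""
        rng = np.random.default_rng(42)
        w = rng.normal(size=N)
        f, p = sp_periodogram(w, fs=FS, window="boxcar")
        sel = (f >= 0.5) & (f <= 8.0)
        q = p[sel] / p[sel].sum()
        expected = float(-(q * np.log(q)).sum())
        assert spectral_entropy(w, FS) == pytest.approx(expected, rel=1e-9)
        # broadband noise sits close to (but below) the ln(n_bins) maximum
        assert expected > 0.75 * np.log(sel.sum())


class TestSlidingDFT:
    def test_zero_stream_stays_zero(self):
        s = SlidingDFT(N, DEFAULT_BANDS.tracked_bins(FS))
        for _ in range(600):
            s.update(0.0)
        assert np.all(s.coeffs == 0.0)

    def test_random_stream_tracks_direct_dft(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=3000)
        s = SlidingDFT(N, DEFAULT_BANDS.tracked_bins(FS))
        for i, v in enumerate(x):
            s.update(v)
            if s.ready and i % 17 == 0:
                direct = np.fft.rfft(s.window())[s.bins]
                scale = np.abs(direct).max()
                assert np.abs(s.coeffs - direct).max() < 1e-6 * scale

    def test_impulse_leaves_cleanly(self):
        s = SlidingDFT(N, DEFAULT_BANDS.tracked_bins(FS), renorm_interval=10**9)
        for _ in range(N):
            s.update(0.0)
        s.update(1.0)
        assert np.abs(s.coeffs).max() > 0.5
        for _ in range(N):
            s.update(0.0)
        assert np.abs(s.coeffs).max() < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(seed=st.integers(0, 10**6))
    def test_property_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=700) * rng.uniform(0.1, 10)
        s = SlidingDFT(N, DEFAULT_BANDS.tracked_bins(FS), renorm_interval=4096)
        for v in x:
            s.update(v)
        direct = np.fft.rfft(s.window())[s.bins]
        assert np.abs(s.coeffs - direct).max() < 1e-6 * max(
            np.abs(direct).max(), 1e-12
        )

    def test_op_count_constant_per_sample(self):
        """Amortized per-sample cost tracks the number of tracked bins,
        not the stream length and not N log N."""
        bins = DEFAULT_BANDS.tracked_bins(FS)
        s1 = SlidingDFT(N, bins, renorm_interval=10**9)
        for v in np.random.default_rng(0).normal(size=500):
            s1.update(v)
        per_sample_1 = s1.op_count / 500
        s2 = SlidingDFT(N, bins, renorm_interval=10**9)
        for v in np.random.default_rng(1).normal(size=2000):
            s2.update(v)
        per_sample_2 = s2.op_count / 2000
        assert per_sample_1 == per_sample_2  # independent of stream length
        assert per_sample_1 == 8 * len(bins) + 8
        # far below an FFT per sample
        assert per_sample_1 < 5 * N * np.log2(N)


class TestExtractFeatures:
    def test_window_counts(self):
        cfg = SyntheticConfig(duration=5.12, fog_episode_rate=0.0, seed=0)
        rec, _ = generate_recording(cfg)
        assert len(rec) == 512
        one = extract_features(
            rec, BandDefinition(), hop=999
        )
        assert len(one) == 1
        three = extract_features(rec, hop=128)
        assert len(three) == 3

    def test_short_recording_warns_empty(self):
        cfg = SyntheticConfig(duration=1.0, fog_episode_rate=0.0, seed=0)
        rec, _ = generate_recording(cfg)
        with pytest.warns(UserWarning, match="shorter than one window"):
            out = extract_features(rec)
        assert len(out) == 0

    def test_trembling_windows_have_higher_freeze_index(self, short_recording):
        rec, _ = short_recording
        feats = extract_features(rec, hop=32)
        fog = feats.labels == int(FogLabel.FOG)
        assert fog.any() and (~fog).any()
        assert (
            feats.matrix[fog, 0].mean() > 10 * feats.matrix[~fog, 0].mean()
        )

    def test_streaming_matches_batch(self, short_recording):
        rec, _ = short_recording
        fb = extract_features(rec, hop=64, mode="batch")
        fs_ = extract_features(rec, hop=64, mode="stream")
        rel = np.abs(fb.matrix - fs_.matrix) / np.maximum(
            np.abs(fb.matrix), 1e-12
        )
        assert rel.max() < 1e-9
        np.testing.assert_array_equal(fb.labels, fs_.labels)

    def test_window_label_majority_ties_to_fog(self):
        fog, nofog, un = FogLabel.FOG, FogLabel.NO_FOG, FogLabel.UNANNOTATED
        assert window_label(np.array([1, 1, 2], dtype=np.int8)) == nofog
        assert window_label(np.array([1, 2, 2], dtype=np.int8)) == fog
        assert window_label(np.array([1, 1, 2, 2], dtype=np.int8)) == fog
        assert window_label(np.array([0, 0, 1], dtype=np.int8)) == un

    def test_streaming_extractor_not_ready_flagged(self):
        ext = StreamingFeatureExtractor(FS)
        ext.update(np.array([0.1, 0.2, 0.3]))
        assert not ext.ready
        with pytest.raises(ValidationError, match="warmed"):
            ext.features()
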