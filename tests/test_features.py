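"""Feature extraction: oracles for LZ76 and word entropies, spectral and
moment checks, and scale-invariance properties."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from hrca.core import CHANNELS, SwallowSegment
from hrca.features import (
    FEATURE_NAMES,
    binarize_median,
    channel_features,
    entropy_rate,
    extract_features,
    lz76_count,
    lz_complexity,
    spectral_features,
    time_features,
    wavelet_entropy,
    wavelet_entropy_from_energies,
    word_entropies,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def lz76_brute_force(bits):
    """Naive LZ76 exhaustive-history parser: character-by-character scanning,
    no library substring search."""
    s = list(bits)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and _occurs(s, i, k):
            k += 1
        c += 1
        i += k
    return c


def _occurs(s, i, k):
    """Does s[i:i+k] occur anywhere in s[:i+k-1] (overlap allowed)?"""
    end = i + k - 1
    for start in range(end - k + 1):
        if all(s[start + j] == s[i + j] for j in range(k)):
            return True
    return False


def word_entropy_naive(symbols, length):
    """Dictionary-counting oracle for the entropy of overlapping words."""
    from collections import Counter

    words = [tuple(symbols[j : j + length]) for j in range(len(symbols) - length + 1)]
    counts = Counter(words)
    total = sum(counts.values())
    probs = [c / total for c in counts.values()]
    entropy = -sum(p * np.log(p) for p in probs)
    perc = sum(1 for c in counts.values() if c == 1) / total
    return entropy, perc


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity
# ---------------------------------------------------------------------------


class TestLZComplexity:
    def test_reference_string_parses_to_six_phrases(self):
        bits = [int(c) for c in "0001101001000101"]
        assert lz76_count(bits) == 6
        assert lz76_brute_force(bits) == 6

    def test_constant_sequence_is_minimal(self):
        # exhaustive history of 0^n is {0, 0...0}: two components
        assert lz76_count([0] * 64) == 2
        x = np.zeros(64)
        assert lz_complexity(x) == pytest.approx(2 * np.log2(64) / 64)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_oracle(self, bits):
        assert lz76_count(bits) == lz76_brute_force(bits)

    def test_random_sequence_normalizes_near_one(self, rng):
        x = rng.standard_normal(100_000)
        assert lz_complexity(x) == pytest.approx(1.0, abs=0.05)

    def test_median_binarization_sends_ties_up(self):
        assert binarize_median(np.array([1.0, 1.0, 2.0])).tolist() == [1, 1, 1]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            lz_complexity(np.array([1.0]))


# ---------------------------------------------------------------------------
# entropy rate (corrected conditional entropy)
# ---------------------------------------------------------------------------


class TestEntropyRate:
    def test_word_entropies_match_naive_counting(self, rng):
        symbols = rng.integers(0, 5, 400)
        fast_e, fast_p = word_entropies(symbols, l_max=4)
        for L in range(1, 5):
            e, p = word_entropy_naive(symbols.tolist(), L)
            assert fast_e[L - 1] == pytest.approx(e, abs=1e-12)
            assert fast_p[L - 1] == pytest.approx(p, abs=1e-12)

    def test_periodic_signal_is_regular(self):
        t = np.arange(8000)
        assert entropy_rate(np.sin(2 * np.pi * t / 40)) >= 0.9

    def test_iid_noise_is_irregular(self, rng):
        assert entropy_rate(rng.uniform(size=10_000)) <= 0.2

    def test_constant_signal_is_maximally_regular(self):
        assert entropy_rate(np.full(2000, 3.7)) == 1.0

    def test_short_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            entropy_rate(rng.standard_normal(500))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25)
    def test_index_bounded_in_unit_interval(self, seed):
        x = np.random.default_rng(seed).standard_normal(1500)
        assert 0.0 <= entropy_rate(x) <= 1.0


# ---------------------------------------------------------------------------
# time / frequency / time-frequency domains
# ---------------------------------------------------------------------------


class TestTimeFeatures:
    def test_alternating_signal_has_zero_skewness(self):
        x = np.tile([1.0, -1.0], 50)
        _, skew, _ = time_features(x)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_is_three(self, rng):
        x = rng.standard_normal(1_000_000)
        _, _, kurt = time_features(x)
        assert kurt == pytest.approx(3.0, abs=0.02)

    def test_constant_signal_policy(self):
        sd, skew, kurt = time_features(np.ones(100))
        assert sd == 0.0 and np.isnan(skew) and np.isnan(kurt)


class TestSpectralFeatures:
    def test_pure_tone_line_spectrum(self):
        fs = 4000.0
        x = np.sin(2 * np.pi * 250.0 * np.arange(8192) / fs)
        peak, centroid, bandwidth = spectral_features(x, fs)
        assert peak == pytest.approx(250.0, abs=fs / 256)
        assert centroid == pytest.approx(250.0, rel=0.02)
        assert bandwidth <= 2 * fs / 256  # at most the spectral resolution scale

    def test_white_noise_centroid_is_quarter_rate(self, rng):
        fs = 4000.0
        x = rng.standard_normal(200_000)
        _, centroid, _ = spectral_features(x, fs)
        assert centroid == pytest.approx(fs / 4, rel=0.05)

    def test_two_equal_tones_average_centroid(self):
        fs = 4000.0
        t = np.arange(65536) / fs
        x = np.sin(2 * np.pi * 200 * t) + np.sin(2 * np.pi * 600 * t)
        _, centroid, _ = spectral_features(x, fs)
        assert centroid == pytest.approx(400.0, rel=0.03)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(1000), 4000.0)


class TestWaveletEntropy:
    def test_narrowband_tone_has_low_entropy(self):
        fs = 4000.0
        x = np.sin(2 * np.pi * 1200.0 * np.arange(4096) / fs)
        assert wavelet_entropy(x) < 0.15

    def test_equal_energy_subbands_give_log_k(self):
        # build coefficient sets with equal energy in k subbands and
        # reconstruct; decomposing the reconstruction recovers them
        levels = 3
        n = 2**10
        template = pywt.wavedec(np.zeros(n), "dmey", mode="periodization", level=levels)
        rng = np.random.default_rng(0)
        coeffs = []
        for c in template:
            block = rng.standard_normal(len(c))
            coeffs.append(block / np.linalg.norm(block))  # unit energy per subband
        x = pywt.waverec(coeffs, "dmey", mode="periodization")
        k = len(coeffs)
        assert wavelet_entropy(x, levels=levels) == pytest.approx(np.log(k), abs=0.05)

    def test_entropy_from_energies_degenerate(self):
        assert wavelet_entropy_from_energies([5.0, 0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            wavelet_entropy_from_energies([0.0, 0.0])

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(4096)
        assert wavelet_entropy(3.7 * x) == pytest.approx(wavelet_entropy(x), rel=1e-9)


# ---------------------------------------------------------------------------
# the 36-feature vector
# ---------------------------------------------------------------------------


def _segment_from(channels, fs=4000.0):
    return SwallowSegment(participant_id="P1", material="water", channels=channels, fs=fs)


class TestExtractFeatures:
    def test_exactly_36_named_values(self, rng):
        channels = {c: rng.standard_normal(4000) for c in CHANNELS}
        vector = extract_features(_segment_from(channels))
        assert len(vector) == 36
        assert set(vector) == {f"{f}_{c}" for f in FEATURE_NAMES for c in CHANNELS}
        assert all(np.isfinite(v) for v in vector.values())

    def test_channel_permutation_permutes_names(self, rng):
        sig = {c: rng.standard_normal(4000) for c in CHANNELS}
        swapped = dict(sig)
        swapped["MIC"], swapped["AP"] = sig["AP"], sig["MIC"]
        v1 = extract_features(_segment_from(sig))
        v2 = extract_features(_segment_from(swapped))
        for f in FEATURE_NAMES:
            assert v2[f"{f}_MIC"] == v1[f"{f}_AP"]
            assert v2[f"{f}_AP"] == v1[f"{f}_MIC"]

    def test_deterministic(self, rng):
        channels = {c: rng.standard_normal(4000) for c in CHANNELS}
        seg = _segment_from(channels)
        assert extract_features(seg) == extract_features(seg)

    @pytest.mark.parametrize("scale", [0.25, -3.0])
    def test_scale_invariances(self, rng, scale):
        x = rng.standard_normal(4096)
        a = channel_features(x, 4000.0)
        b = channel_features(scale * x, 4000.0)
        assert b["std_dev"] == pytest.approx(abs(scale) * a["std_dev"], rel=1e-9)
        for name in ("skewness", "kurtosis", "wavelet_entropy", "lz_complexity", "entropy_rate"):
            expected = a[name]
            if name == "skewness" and scale < 0:
                expected = -expected
            if name == "lz_complexity" and scale < 0:
                # negation flips the median binarization of ties only; values match
                assert b[name] == pytest.approx(expected, abs=0.02)
                continue
            assert b[name] == pytest.approx(expected, abs=1e-6)
        for name in ("peak_frequency", "spectral_centroid", "bandwidth"):
            assert b[name] == pytest.approx(a[name], rel=1e-6)


class TestPaddingMechanism:
    def test_null_padding_lowers_lzc_and_raises_regularity(self, rng):
        """Longer non-swallow stretches around a fixed burst make the signal
        more predictable: Lempel-Ziv complexity falls, the entropy-rate
        regularity index rises (the pushbutton-segmentation mechanism)."""
        from scipy.signal import lfilter

        fs = 4000.0
        burst = np.sin(2 * np.pi * 300 * np.arange(2000) / fs) * np.hanning(2000)
        burst += 0.05 * rng.standard_normal(2000)
        lzc, rho = [], []
        for pad in (500, 4000, 16000):
            # quiet stretches are smooth (denoised) residual noise: strongly
            # autocorrelated, so they binarize into long runs
            quiet = 0.05 * lfilter([1.0], [1.0, -0.98], rng.standard_normal(pad))
            x = np.r_[quiet, burst, quiet]
            lzc.append(lz_complexity(x))
            rho.append(entropy_rate(x))
        assert lzc[0] > lzc[1] > lzc[2]
        assert rho[0] < rho[1] < rho[2]
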