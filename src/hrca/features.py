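"""The 9-feature-per-channel HRCA representation (36 features per swallow).

Domains and features
--------------------
* time: standard deviation, skewness, kurtosis (non-excess; Gaussian -> 3)
* frequency (Welch PSD): peak frequency, spectral centroid, bandwidth
* time-frequency: wavelet entropy of the discrete-Meyer subband energies
* information-theoretic: normalized Lempel-Ziv complexity (LZ76 on the
  median-binarized signal) and a normalized entropy-rate regularity index
  based on corrected conditional entropy (higher = more regular signal).

Degenerate inputs (constant or zero-energy channels) yield NaN for the
affected features; downstream stages drop missing values per feature with a
logged count.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from hrca.core import CHANNELS, SwallowSegment

FEATURE_NAMES: Tuple[str, ...] = (
    "std_dev",
    "skewness",
    "kurtosis",
    "peak_frequency",
    "spectral_centroid",
    "bandwidth",
    "wavelet_entropy",
    "lz_complexity",
    "entropy_rate",
)

FEATURE_DOMAINS = {
    "std_dev": "time",
    "skewness": "time",
    "kurtosis": "time",
    "peak_frequency": "frequency",
    "spectral_centroid": "frequency",
    "bandwidth": "frequency",
    "wavelet_entropy": "time-frequency",
    "lz_complexity": "information-theoretic",
    "entropy_rate": "information-theoretic",
}

#: documented minimum length for the 10-bin entropy-rate quantization
ENTROPY_RATE_MIN_LENGTH = 1000


def time_features(x: np.ndarray) -> Tuple[float, float, float]:
    """Sample SD plus standardized third and fourth central moments.

    Kurtosis is reported non-excess (a Gaussian gives ~3).  A constant signal
    has SD 0 and undefined (NaN) skewness and kurtosis.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0, np.nan, np.nan
    return (
        sd,
        float(stats.skew(x)),
        float(stats.kurtosis(x, fisher=False)),
    )


def _welch(x: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    nperseg = min(256, len(x))
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def spectral_features(x: np.ndarray, fs: float) -> Tuple[float, float, float]:
    """Peak frequency, spectral centroid and RMS bandwidth from a Welch PSD.

    centroid = sum(f * P) / sum(P); bandwidth = sqrt(sum((f - centroid)^2 * P)
    / sum(P)).  Welch settings: Hann window, 256-sample segments, 50% overlap
    (>= 15 Hz resolution at 4 kHz).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError("need at least 64 samples")
    if not np.any(x):
        raise ValueError("all-zero signal has no defined spectrum")
    f, p = _welch(x, fs)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum")
    centroid = float((f * p).sum() / total)
    bandwidth = float(np.sqrt((((f - centroid) ** 2) * p).sum() / total))
    return float(f[int(np.argmax(p))]), centroid, bandwidth


def wavelet_entropy_from_energies(energies: Sequence[float]) -> float:
    """Shannon entropy (nats) of a subband relative-energy distribution."""
    e = np.asarray(energies, dtype=float)
    total = e.sum()
    if total <= 0:
        raise ValueError("zero-energy signal")
    p = e[e > 0] / total
    return float(-(p * np.log(p)).sum())


def wavelet_entropy(x: np.ndarray, wavelet: str = "dmey", levels: int = 10) -> float:
    """Wavelet entropy over the multilevel discrete-Meyer subband energies.

    Subbands are the final approximation plus every detail level; the
    requested depth is capped at the signal's maximum decomposition depth.
    Near 0 when energy concentrates in one subband; invariant to amplitude
    scaling.
    """
    from hrca.preprocess import get_wavelet

    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet).dec_len)
    levels = max(1, min(levels, max_level))
    coeffs = pywt.wavedec(x, get_wavelet(wavelet), mode="periodization", level=levels)
    energies = [float(np.sum(c**2)) for c in coeffs]
    return wavelet_entropy_from_energies(energies)


def lz76_count(sequence: Sequence[int]) -> int:
    """LZ76 exhaustive-history production count of a binary sequence.

    Each production is the shortest new phrase that cannot be copied from the
    previously seen text (Lempel-Ziv 1976 / Kaspar-Schuster parsing).
    """
    s = "".join("1" if int(b) else "0" for b in np.asarray(sequence))
    n = len(s)
    c = 0
    i = 0
    while i < n:
        # grow the candidate phrase until it cannot be copied from the text
        # seen so far (C-level substring search keeps this fast)
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def binarize_median(x: np.ndarray) -> np.ndarray:
    """Binarize by the median; ties (x == median) map to 1."""
    x = np.asarray(x, dtype=float)
    return (x >= np.median(x)).astype(np.int8)


def lz_complexity(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity ``c(n) * log2(n) / n``.

    The signal is median-binarized first; an i.i.d. random sequence
    approaches 1, a constant signal attains the minimum ``log2(n)/n``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    c = lz76_count(binarize_median(x))
    return float(c * np.log2(n) / n)


def word_entropies(symbols: np.ndarray, l_max: int) -> Tuple[np.ndarray, np.ndarray]:
    """Shannon entropy E(L) (nats) of overlapping L-words, and the fraction
    of words occurring exactly once, for L = 1..l_max.

    This is the building block of the corrected-conditional-entropy
    regularity index; exposed separately so it can be checked against naive
    dictionary counting.
    """
    symbols = np.asarray(symbols, dtype=np.int64)
    n = len(symbols)
    entropies = np.zeros(l_max)
    perc = np.zeros(l_max)
    base = int(symbols.max()) + 1
    for L in range(1, l_max + 1):
        if n - L + 1 < 1:
            entropies[L - 1] = np.nan
            perc[L - 1] = np.nan
            continue
        # encode each L-word as an integer in base `base`
        codes = np.zeros(n - L + 1, dtype=np.int64)
        for j in range(L):
            codes = codes * base + symbols[j : n - L + 1 + j]
        _, counts = np.unique(codes, return_counts=True)
        probs = counts / counts.sum()
        entropies[L - 1] = float(-(probs * np.log(probs)).sum())
        perc[L - 1] = float((counts == 1).sum() / counts.sum())
    return entropies, perc


def entropy_rate(
    x: np.ndarray, n_bins: int = 10, l_max: int = 10, min_length: int = ENTROPY_RATE_MIN_LENGTH
) -> float:
    """Normalized regularity index in [0, 1] (higher = more regular).

    The de-meaned signal is quantized into ``n_bins`` uniform amplitude bins;
    the corrected conditional entropy ``CCE(L) = E(L) - E(L-1) + perc(L) *
    E(1)`` (``perc`` = fraction of L-words seen once, correcting the
    vanishing-entropy artifact of short records) is minimized over word
    lengths and normalized by ``E(1)``; the index is ``1 - min_L
    NCCE(L)``.  A constant signal is maximally regular by convention
    (index 1).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < min_length:
        raise ValueError(f"need at least {min_length} samples, got {len(x)}")
    x = x - x.mean()
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 1.0
    symbols = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(np.int64), n_bins - 1)
    entropies, perc = word_entropies(symbols, l_max)
    e1 = entropies[0]
    if e1 <= 0:
        return 1.0
    ncce = np.empty(l_max)
    ncce[0] = 1.0
    for L in range(2, l_max + 1):
        cce = entropies[L - 1] - entropies[L - 2] + perc[L - 1] * e1
        ncce[L - 1] = cce / e1
    rho = 1.0 - float(np.nanmin(ncce))
    return float(np.clip(rho, 0.0, 1.0))


_FEATURE_FUNCS_NEED_FS = {"peak_frequency", "spectral_centroid", "bandwidth"}


def channel_features(x: np.ndarray, fs: float, wavelet_levels: int = 10) -> Dict[str, float]:
    """All 9 features for one channel; degenerate features become NaN."""
    out: Dict[str, float] = {}
    sd, skew, kurt = time_features(x)
    out["std_dev"], out["skewness"], out["kurtosis"] = sd, skew, kurt
    try:
        pk, cent, bw = spectral_features(x, fs)
    except ValueError:
        pk = cent = bw = np.nan
    out["peak_frequency"], out["spectral_centroid"], out["bandwidth"] = pk, cent, bw
    try:
        out["wavelet_entropy"] = wavelet_entropy(x, levels=wavelet_levels)
    except ValueError:
        out["wavelet_entropy"] = np.nan
    out["lz_complexity"] = lz_complexity(x)
    try:
        out["entropy_rate"] = entropy_rate(x)
    except ValueError:
        out["entropy_rate"] = np.nan
    return out


def extract_features(
    segment: SwallowSegment, wavelet_levels: int = 10
) -> Dict[str, float]:
    """The 36-value feature vector of a (preprocessed) segment.

    Keys are ``<feature>_<channel>`` for the 9 features on each of MIC, AP,
    SI, ML.  Deterministic.
    """
    vector: Dict[str, float] = {}
    for c in CHANNELS:
        feats = channel_features(segment.channels[c], segment.fs, wavelet_levels)
        for name, value in feats.items():
            vector[f"{name}_{c}"] = value
    return vector


def features_from_segments(
    segments, wavelet_levels: int = 10
) -> "pd.DataFrame":
    """Feature table (key columns + 36 feature columns) from segments."""
    import pandas as pd

    rows = []
    for seg in segments:
        row = {
            "participant_id": seg.participant_id,
            "swallow_index": seg.swallow_index,
            "material": seg.material,
        }
        row.update(extract_features(seg, wavelet_levels))
        rows.append(row)
    return pd.DataFrame(rows)
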