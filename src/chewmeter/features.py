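"""Per-epoch time/frequency feature extraction (38 features).

The intake classifier works on a 38-dimensional feature vector per epoch:
19 time-domain descriptors of the raw (demeaned) waveform and 19
frequency-domain descriptors of its Hann-window periodogram.  The split
covers the low-frequency chewing band as well as speech/motion content
higher up, which is what separates chewing epochs from talking and
movement.

Feature names and order are stable across the package version; exporters
rely on that.

Degenerate-input conventions: amplitude entropy of a constant epoch is 0;
all spectral descriptors of an all-zero epoch are 0 (dominant frequency
included); skewness/kurtosis are 0 whenever the relevant variance is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

N_FEATURES = 38

#: Band edges (Hz) for relative band power; bands beyond Nyquist report 0.
POWER_BANDS: Tuple[Tuple[float, float], ...] = (
    (0.0, 1.0),
    (1.0, 2.0),
    (2.0, 3.0),
    (3.0, 5.0),
    (5.0, 10.0),
    (10.0, 50.0),
    (50.0, 500.0),
    (500.0, np.inf),  # upper edge clipped to fs/2
)

TIME_FEATURE_NAMES = [
    "mav",
    "rms",
    "variance",
    "std",
    "peak_to_peak",
    "mad",
    "skewness",
    "kurtosis",
    "zero_crossings",
    "mean_crossing_rate",
    "slope_sign_changes",
    "waveform_length",
    "log_energy",
    "amplitude_entropy",
    "p10",
    "p25",
    "p75",
    "p90",
    "iqr",
]

FREQ_FEATURE_NAMES = (
    ["total_power"]
    + [f"relpower_{lo:g}_{('inf' if np.isinf(hi) else f'{hi:g}')}hz" for lo, hi in POWER_BANDS]
    + [
        "dominant_freq",
        "dominant_power",
        "spectral_centroid",
        "spectral_spread",
        "spectral_entropy",
        "edge_freq_50",
        "edge_freq_90",
        "edge_freq_95",
        "spectral_skewness",
        "spectral_kurtosis",
    ]
)

FEATURE_NAMES: List[str] = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES
assert len(FEATURE_NAMES) == N_FEATURES


@dataclass
class FeatureVector:
    values: np.ndarray
    names: List[str]
    epoch_ref: Tuple[str, int] = ("", -1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")


def _safe_moment(x: np.ndarray, func) -> float:
    # constant / near-constant epochs: higher moments are 0 by convention
    if np.ptp(x) == 0 or np.std(x) < 1e-12 * (np.abs(x).max() + 1.0):
        return 0.0
    value = float(func(x))
    return value if np.isfinite(value) else 0.0


def _time_features(x: np.ndarray, fs: float) -> List[float]:
    duration = len(x) / fs
    diffs = np.diff(x)
    signs = np.sign(x)
    nz = signs != 0
    zero_crossings = float(np.sum(np.abs(np.diff(signs[nz])) == 2))
    centered = x - x.mean()
    csigns = np.sign(centered)
    cnz = csigns != 0
    mean_crossings = float(np.sum(np.abs(np.diff(csigns[cnz])) == 2))
    dsigns = np.sign(diffs)
    dnz = dsigns != 0
    slope_sign_changes = float(np.sum(np.abs(np.diff(dsigns[dnz])) == 2))

    # Shannon entropy (nats) of a 16-bin amplitude histogram
    if np.ptp(x) == 0:
        amp_entropy = 0.0
    else:
        hist, _ = np.histogram(x, bins=16)
        p = hist / hist.sum()
        p = p[p > 0]
        amp_entropy = float(-(p * np.log(p)).sum())

    energy = float(np.sum(x**2))
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    return [
        float(np.mean(np.abs(x))),
        float(np.sqrt(np.mean(x**2))),
        float(np.var(x)),
        float(np.std(x)),
        float(np.ptp(x)),
        float(np.median(np.abs(x - np.median(x)))),
        _safe_moment(x, stats.skew),
        _safe_moment(x, stats.kurtosis),
        zero_crossings,
        mean_crossings / duration,
        slope_sign_changes,
        float(np.sum(np.abs(diffs))),
        float(np.log(energy + 1e-30)),
        amp_entropy,
        float(p10),
        float(p25),
        float(p75),
        float(p90),
        float(p75 - p25),
    ]


def _freq_features(x: np.ndarray, fs: float) -> List[float]:
    freqs, psd = sps.periodogram(x, fs=fs, window="hann")
    total = float(np.sum(psd))
    if total <= 0:
        return [0.0] * len(FREQ_FEATURE_NAMES)

    band_powers = []
    nyq = fs / 2.0
    for lo, hi in POWER_BANDS:
        hi = min(hi, nyq)
        if hi <= lo:
            band_powers.append(0.0)
            continue
        mask = (freqs >= lo) & (freqs < hi)
        if hi >= nyq:  # topmost usable band owns the Nyquist bin
            mask |= freqs == hi
        band_powers.append(float(np.sum(psd[mask]) / total))

    k = int(np.argmax(psd))
    dominant_freq = float(freqs[k])
    dominant_power = float(psd[k])

    p = psd / total
    centroid = float(np.sum(freqs * p))
    spread = float(np.sqrt(np.sum((freqs - centroid) ** 2 * p)))
    pnz = p[p > 0]
    spectral_entropy = float(-(pnz * np.log(pnz)).sum())

    cumulative = np.cumsum(p)
    edges = [float(freqs[np.searchsorted(cumulative, q)]) for q in (0.50, 0.90, 0.95)]

    if spread == 0:
        spec_skew = spec_kurt = 0.0
    else:
        spec_skew = float(np.sum(((freqs - centroid) / spread) ** 3 * p))
        spec_kurt = float(np.sum(((freqs - centroid) / spread) ** 4 * p) - 3.0)

    return (
        [total]
        + band_powers
        + [dominant_freq, dominant_power, centroid, spread, spectral_entropy]
        + edges
        + [spec_skew, spec_kurt]
    )


def compute_features(samples: Sequence[float], fs: float, epoch_ref=("", -1)) -> FeatureVector:
    """Compute the 38-feature vector for one epoch of raw (demeaned) signal."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite samples")
    if fs <= 0:
        raise ValueError("fs must be positive")
    values = np.asarray(_time_features(x, fs) + _freq_features(x, fs))
    return FeatureVector(values=values, names=list(FEATURE_NAMES), epoch_ref=tuple(epoch_ref))


def feature_matrix(epoch_samples: Sequence[Sequence[float]], fs: float) -> np.ndarray:
    """Stack feature vectors for a sequence of epochs into an (n, 38) array."""
    return np.vstack([compute_features(s, fs).values for s in epoch_samples])


def export_feature_table(
    features: np.ndarray,
    visit_ids: Sequence[str],
    indices: Sequence[int],
    labels: Sequence[int],
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with visit/index/label columns first."""
    df = pd.DataFrame(features, columns=FEATURE_NAMES)
    df.insert(0, "label", list(labels))
    df.insert(0, "epoch_index", list(indices))
    df.insert(0, "visit", list(visit_ids))
    return df
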