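"""Per-event feature extraction: spatial statistics, autocorrelation peaks,
Welch spectral peaks and band powers.

Each 101-sample axis channel of an event segment yields 24 features:

* 6 statistical moments — mean, variance, standard deviation, RMS, skewness
  and kurtosis, all population-normalised (divisor N); kurtosis is the raw
  fourth standardised moment (3 for a Gaussian), and skewness/kurtosis are
  defined as 0 for a constant channel.
* 3 autocorrelation features — position of the main peak (always lag 0 of
  the normalised autocovariance), and position and amplitude of the second
  detected peak, positions in seconds.
* 12 spectral-peak features — positions (Hz) and amplitudes of the 6
  tallest Welch-PSD peaks, zero-padded when fewer exist.
* 3 band powers — PSD integrals over 0.5-5, 5-10 and 10-20 Hz.

The 24 features over 3 axes are interleaved axis-fastest
(``f1.x, f1.y, f1.z, f2.x, ...``) into a 72-value vector whose name order
is identical for every event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .segmentation import EventSegment

__all__ = [
    "PsdEstimate",
    "FeatureVector",
    "FEATURE_NAMES",
    "AXIS_FEATURE_NAMES",
    "TOTAL_ACCELERATION_NAMES",
    "DEFAULT_BANDS",
    "spatial_statistics",
    "autocorrelation_features",
    "welch_psd",
    "spectral_peak_features",
    "band_powers",
    "extract_event_features",
    "total_acceleration_features",
    "iterative_peak_search",
]

#: PSD integration bands in Hz: locomotion, impact, and high-frequency content.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.5, 5.0), (5.0, 10.0), (10.0, 20.0))

AXIS_FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "variance",
    "std",
    "rms",
    "skewness",
    "kurtosis",
    "acf_main_pos",
    "acf_peak2_pos",
    "acf_peak2_amp",
    *(f"psd_peak{i}_pos" for i in range(1, 7)),
    *(f"psd_peak{i}_amp" for i in range(1, 7)),
    "bandpower_0.5_5",
    "bandpower_5_10",
    "bandpower_10_20",
)

#: The 72 feature names in the fixed interleaved order f1.x, f1.y, f1.z, f2.x, ...
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{name}.{axis}" for name in AXIS_FEATURE_NAMES for axis in "xyz"
)


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided power spectral density on an ascending frequency grid."""

    frequencies: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        d = np.asarray(self.densities, dtype=float)
        if f.shape != d.shape or f.ndim != 1:
            raise ValueError("frequencies and densities must be equal-length 1-D arrays")
        if f[0] != 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must start at 0 and be strictly ascending")
        if np.any(d < -1e-15):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "densities", np.maximum(d, 0.0))


@dataclass(frozen=True)
class FeatureVector:
    """Ordered per-event feature values with their names and provenance."""

    values: np.ndarray
    names: tuple[str, ...]
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.shape[0] != len(self.names):
            raise ValueError("values and names must have matching length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "values", values)


def spatial_statistics(channel: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Population moments of one channel: (mean, var, std, rms, skew, kurt).

    All moments use divisor N.  Kurtosis is non-excess (Gaussian -> 3).
    For a zero-variance channel skewness and kurtosis are defined as 0.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("channel must be 1-D with at least 2 samples")
    n = x.size
    mu = float(np.sum(x) / n)
    centred = x - mu
    var = float(np.sum(centred**2) / n)
    std = float(np.sqrt(var))
    rms = float(np.sqrt(np.sum(np.abs(x) ** 2) / n))
    if std == 0.0:
        return mu, var, std, rms, 0.0, 0.0
    skew = float(np.sum(centred**3) / (n * std**3))
    kurt = float(np.sum(centred**4) / (n * std**4))
    return mu, var, std, rms, skew, kurt


def iterative_peak_search(
    values: np.ndarray,
    positions: np.ndarray,
    min_distance: float,
    max_peaks: int,
) -> list[tuple[float, float]]:
    """Greedy tallest-first peak selection with an exclusion radius.

    Candidates are local maxima (endpoints compared against their single
    neighbour; interior samples must be >= both neighbours and strictly
    greater than at least one, so constant stretches yield no peaks).
    The tallest candidate is accepted (amplitude ties broken by the
    earliest position), every candidate within ``min_distance`` of it is
    discarded, and the procedure repeats until ``max_peaks`` peaks are
    found or no candidates remain.

    Returns ``(position, amplitude)`` pairs in detection order, i.e.
    non-increasing amplitude.
    """
    v = np.asarray(values, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = v.size
    if n == 0:
        return []
    if n == 1:
        candidates = np.array([], dtype=int)
    else:
        left_ok = np.empty(n, dtype=bool)
        right_ok = np.empty(n, dtype=bool)
        strict = np.zeros(n, dtype=bool)
        left_ok[0] = True
        left_ok[1:] = v[1:] >= v[:-1]
        right_ok[-1] = True
        right_ok[:-1] = v[:-1] >= v[1:]
        strict[0] = v[0] > v[1]
        strict[-1] = v[-1] > v[-2]
        strict[1:-1] = (v[1:-1] > v[:-2]) | (v[1:-1] > v[2:])
        candidates = np.flatnonzero(left_ok & right_ok & strict)

    peaks: list[tuple[float, float]] = []
    remaining = list(candidates)
    while remaining and len(peaks) < max_peaks:
        best = max(remaining, key=lambda i: (v[i], -i))
        peaks.append((float(pos[best]), float(v[best])))
        remaining = [i for i in remaining if abs(pos[i] - pos[best]) > min_distance]
    return peaks


def autocorrelation_features(
    channel: np.ndarray, fs: float, exclusion_lags: int | None = None
) -> tuple[float, float, float]:
    """Autocorrelation peak features: (main-peak pos, 2nd-peak pos, 2nd-peak amp).

    The biased sample autocovariance over lags 0..N-1 is normalised so the
    zero-lag value is 1; peaks are selected greedily with an exclusion
    radius of ``max(1, round(0.3 * T * fs))`` lags around each accepted
    peak, where T = 1/fs is one sample period.  Positions are in seconds.
    A zero-variance channel returns (0, 0, 0).
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("channel must be 1-D with at least 2 samples")
    n = x.size
    centred = x - x.mean()
    denom = float(np.sum(centred**2))
    if denom == 0.0:
        return 0.0, 0.0, 0.0
    acf = np.correlate(centred, centred, mode="full")[n - 1 :] / denom
    lags = np.arange(n)
    if exclusion_lags is None:
        exclusion_lags = max(1, round(0.3 * (1.0 / fs) * fs))
    peaks = iterative_peak_search(acf, lags, float(exclusion_lags), max_peaks=2)
    main_pos = peaks[0][0] / fs if len(peaks) >= 1 else 0.0
    if len(peaks) >= 2:
        return main_pos, peaks[1][0] / fs, peaks[1][1]
    return main_pos, 0.0, 0.0


def welch_psd(channel: np.ndarray, fs: float) -> PsdEstimate:
    """Welch PSD with 8 sections, 50% overlap and a Hamming window.

    The section length is ``floor(N/4.5)`` (the standard 8-section, 50%
    overlap geometry), rounded down to an even number so the one-sided
    grid ends exactly at fs/2.  Density scaling: the integral of the PSD
    over frequency approximates the signal's total power (variance plus
    squared mean) — no detrending is applied.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel must be 1-D")
    if x.size < 8:
        raise ValueError("channel too short for a Welch section")
    nperseg = max(2, int(x.size / 4.5))
    nperseg -= nperseg % 2
    freqs, dens = welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    freqs[-1] = fs / 2.0  # snap away float error so the grid ends at Nyquist
    return PsdEstimate(frequencies=freqs, densities=dens)


def spectral_peak_features(
    psd: PsdEstimate, n_peaks: int = 6, min_distance_hz: float | None = None
) -> np.ndarray:
    """Positions and amplitudes of the ``n_peaks`` tallest PSD peaks.

    Output is ``[pos_1..pos_n, amp_1..amp_n]`` with peaks in detection
    (amplitude-descending) order, zero-padded when fewer local maxima
    exist.  The default exclusion radius is one grid bin; callers derived
    from an event segment should pass ``max(0.3 * fs / N, df)`` where N is
    the segment length and df the grid spacing.
    """
    f = psd.frequencies
    if min_distance_hz is None:
        min_distance_hz = float(f[1] - f[0]) if f.size > 1 else 0.0
    peaks = iterative_peak_search(psd.densities, f, min_distance_hz, n_peaks)
    out = np.zeros(2 * n_peaks)
    for i, (position, amplitude) in enumerate(peaks):
        out[i] = position
        out[n_peaks + i] = amplitude
    return out


def band_powers(
    psd: PsdEstimate, bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Total PSD power in each band, by trapezoidal integration.

    Band edges are resolved by linear interpolation of the density onto
    the exact edge frequencies, so adjacent bands tile the axis without
    double counting.  Requires the PSD grid to reach the highest band edge.
    """
    f, d = psd.frequencies, psd.densities
    top = max(hi for _, hi in bands)
    if f[-1] < top:
        raise ValueError(
            f"PSD reaches only {f[-1]:g} Hz; bands require coverage to {top:g} Hz"
        )
    powers = np.empty(len(bands))
    for i, (lo, hi) in enumerate(bands):
        inner = f[(f > lo) & (f < hi)]
        grid = np.concatenate(([lo], inner, [hi]))
        powers[i] = np.trapezoid(np.interp(grid, f, d), grid)
    return powers


def _axis_features(channel: np.ndarray, fs: float) -> np.ndarray:
    stats = spatial_statistics(channel)
    acf = autocorrelation_features(channel, fs)
    psd = welch_psd(channel, fs)
    df = float(psd.frequencies[1] - psd.frequencies[0])
    min_dist = max(0.3 * fs / channel.size, df)
    peaks = spectral_peak_features(psd, n_peaks=6, min_distance_hz=min_dist)
    bands = band_powers(psd)
    return np.concatenate([stats, acf, peaks, bands])


def extract_event_features(segment: EventSegment) -> FeatureVector:
    """Assemble the 72-value feature vector of one event segment.

    Per axis: 6 statistical moments, 3 autocorrelation features, 12
    spectral-peak features and 3 band powers (24 values), interleaved
    axis-fastest across the three axes.  Name order is fixed and identical
    for every event (see :data:`FEATURE_NAMES`).
    """
    per_axis = np.stack(
        [_axis_features(segment.data[:, c], segment.fs) for c in range(3)]
    )  # shape (3 axes, 24 features)
    interleaved = per_axis.T.reshape(-1)  # f1.x f1.y f1.z f2.x ...
    return FeatureVector(
        values=interleaved,
        names=FEATURE_NAMES,
        label=segment.label,
        subject_id=segment.subject_id,
    )


TOTAL_ACCELERATION_NAMES: tuple[str, str] = ("total_acc_min", "total_acc_max")


def total_acceleration_features(segment: EventSegment) -> FeatureVector:
    """Baseline 2-value feature set: min and max of the per-sample magnitude."""
    mag = segment.magnitude()
    return FeatureVector(
        values=np.array([mag.min(), mag.max()]),
        names=TOTAL_ACCELERATION_NAMES,
        label=segment.label,
        subject_id=segment.subject_id,
    )
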