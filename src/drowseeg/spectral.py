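"""Frequency-domain features from a Hanning-windowed periodogram.

Per channel-epoch the extractor yields 26 named features: for each of the
five canonical bands the band power, within-band peak frequency, gravity
frequency (spectral centroid) and frequency variability (power-weighted
spectral standard deviation), plus the six pairwise band-power ratios over
the ordered pairs of {delta, theta, alpha, beta} (lower band over higher
band): 4 x 5 + 6 = 26.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .bands import ALL_BANDS, SUB_BANDS, BandSpec

#: Ordered (numerator, denominator) band pairs of the six ratio features.
RATIO_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (a.name, b.name) for a, b in combinations(SUB_BANDS, 2)
)

#: Stable order of the 26 spectral feature names.
SPECTRAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{band.name}_{stat}"
    for band in ALL_BANDS
    for stat in ("power", "peak_freq", "gravity_freq", "freq_var")
) + tuple(f"ratio_{a}_{b}" for a, b in RATIO_PAIRS)


@dataclass
class SpectralEstimate:
    """One-sided PSD on a regular frequency grid from 0 to fs/2."""

    freqs: np.ndarray
    psd: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_mask(self, band: BandSpec) -> np.ndarray:
        return (self.freqs >= band.f_lo) & (self.freqs < band.f_hi)


def periodogram_hann(x: np.ndarray, fs: float) -> SpectralEstimate:
    """Single-taper periodogram of the mean-removed, Hann-windowed series.

    The window power is compensated (density scaling) so that the
    integrated PSD matches the signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("periodogram needs at least 2 s of samples")
    freqs, psd = signal.periodogram(
        x, fs=fs, window="hann", detrend="constant", scaling="density"
    )
    return SpectralEstimate(freqs, psd)


def band_power(est: SpectralEstimate, band: BandSpec) -> float:
    """Integrated PSD over ``[f_lo, f_hi)`` (rectangle rule on the grid)."""
    mask = est.band_mask(band)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}) contains no grid "
            f"frequency at resolution {est.resolution:.4g} Hz"
        )
    return float(est.psd[mask].sum() * est.resolution)


def peak_frequency(est: SpectralEstimate, band: BandSpec) -> float:
    """Frequency of the maximum in-band PSD bin; ties go to the lower bin."""
    mask = est.band_mask(band)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no grid frequency")
    f = est.freqs[mask]
    p = est.psd[mask]
    return float(f[np.argmax(p)])  # argmax returns the first (lowest-f) maximum


def gravity_frequency(est: SpectralEstimate, band: BandSpec) -> float:
    """Power-weighted mean frequency (spectral centroid) within the band."""
    mask = est.band_mask(band)
    p = est.psd[mask]
    total = p.sum()
    if total <= 0:
        return float("nan")
    return float((est.freqs[mask] * p).sum() / total)


def frequency_variability(est: SpectralEstimate, band: BandSpec) -> float:
    """Power-weighted spectral standard deviation within the band."""
    mask = est.band_mask(band)
    p = est.psd[mask]
    total = p.sum()
    if total <= 0:
        return float("nan")
    f = est.freqs[mask]
    centroid = (f * p).sum() / total
    return float(np.sqrt(((f - centroid) ** 2 * p).sum() / total))


def spectral_feature_vector(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = ALL_BANDS,
    ratio_floor: float = 0.0,
) -> dict[str, float]:
    """The 26-feature frequency-domain vector of one channel-epoch.

    Ratios divide the band powers after adding ``ratio_floor`` to both; a
    zero denominator yields NaN rather than infinity.  Ratio features are
    invariant to amplitude scaling of the input.
    """
    est = periodogram_hann(x, fs)
    features: dict[str, float] = {}
    powers: dict[str, float] = {}
    for band in bands:
        p = band_power(est, band)
        powers[band.name] = p
        features[f"{band.name}_power"] = p
        features[f"{band.name}_peak_freq"] = peak_frequency(est, band)
        features[f"{band.name}_gravity_freq"] = gravity_frequency(est, band)
        features[f"{band.name}_freq_var"] = frequency_variability(est, band)
    for a, b in RATIO_PAIRS:
        num = powers[a] + ratio_floor
        den = powers[b] + ratio_floor
        features[f"ratio_{a}_{b}"] = num / den if den > 0 else float("nan")
    return features
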