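"""Nonlinear time-series features on Butterworth sub-bands.

Per channel-epoch the extractor yields 16 named features: the generalized
Hurst exponent (first-order increment-moment scaling), the Higuchi fractal
dimension, the spectral entropy and the permutation entropy, each computed
on the delta, theta, alpha and beta band-passed series.  All four measures
are invariant to positive amplitude scaling: the two scaling exponents are
slopes of log-log regressions, and both entropies operate on normalized
distributions.

Conventions:

* Higuchi: curve lengths ``L_m(k)`` use the Gauss-bracket count
  ``[(N - m) / k]`` and the normalization ``(N - 1) / ([(N - m)/k] k)``; the
  fractal dimension is the slope of ``ln L(k)`` versus ``ln (1/k)``.  The
  regression grid includes k = 1 by default (whose L(1) is the raw curve
  length) for stability; subseries construction runs k = 2..k_max.
* Generalized Hurst: ``K(tau) = <|x(t + tau) - x(t)|>`` for tau = 1..19
  samples; H is the slope of ``ln K`` on ``ln tau``, clipped to [0, 1].
  H = 0.5 for a random walk, 1 for a ramp, 0 for i.i.d. noise.
* Spectral entropy: ``(-sum P_i ln P_i) / N_f`` over the N_f in-band bins of
  the Hann periodogram, with P_i the in-band relative power.  The division
  by the bin *count* N_f follows the source definition; the conventional
  ``ln N_f`` normalizer is available via ``normalizer="log_count"``.
* Permutation entropy: Bandt-Pompe ordinal patterns of order n = 4, lag 1,
  on the series resampled to 64 Hz; ties rank by position (earlier sample
  lower).  Natural logarithm, so the i.i.d. limit is ln(4!) = ln 24.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bands import SUB_BANDS, BandSpec
from .preprocess import bandpass, resample_series
from .spectral import periodogram_hann

#: Stable order of the 16 nonlinear feature names.
NONLINEAR_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{band.name}_{stat}"
    for band in SUB_BANDS
    for stat in ("H", "HFD", "SpEn", "PmEn")
)


@dataclass(frozen=True)
class HiguchiParams:
    k_max: int = 8
    include_k1: bool = True

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


@dataclass(frozen=True)
class HurstParams:
    q: int = 1
    tau_max: int = 19

    def __post_init__(self) -> None:
        if self.q != 1:
            raise ValueError("only the first-order increment moment is supported")
        if self.tau_max < 2:
            raise ValueError("tau_max must be >= 2")

    @property
    def taus(self) -> np.ndarray:
        return np.arange(1, self.tau_max + 1)


@dataclass(frozen=True)
class PermutationParams:
    n: int = 4
    lag: int = 1
    resample_fs: float = 64.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("pattern order n must be >= 2")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")


def higuchi_fd(x: np.ndarray, params: HiguchiParams | None = None) -> float:
    """Higuchi fractal dimension of a series (1 for a line, 2 for noise).

    Returns NaN for a constant series (all curve lengths vanish).
    """
    params = params or HiguchiParams()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 * params.k_max:
        raise ValueError(f"series of {n} samples too short for k_max={params.k_max}")

    k_grid = range(1, params.k_max + 1) if params.include_k1 else range(2, params.k_max + 1)
    ks, lengths = [], []
    for k in k_grid:
        lm = []
        for m in range(1, k + 1):  # initial time, 1-based as in the construction
            sub = x[m - 1:: k]
            n_int = (n - m) // k  # Gauss bracket [(N - m) / k]
            if n_int < 1:
                continue
            dist = np.abs(np.diff(sub[: n_int + 1])).sum()
            lm.append(dist * (n - 1) / (n_int * k) / k)
        if lm:
            ks.append(k)
            lengths.append(np.mean(lm))
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):
        return float("nan")
    slope = np.polyfit(np.log(1.0 / np.asarray(ks, dtype=float)), np.log(lengths), 1)[0]
    return float(slope)


def generalized_hurst(
    x: np.ndarray,
    params: HurstParams | None = None,
    clip: bool = True,
    return_info: bool = False,
):
    """Generalized Hurst exponent from first-order increment moments.

    ``K(tau)`` is the mean absolute increment at lag tau; H is the
    log-log slope over tau = 1..tau_max.  With ``clip`` the estimate is
    clipped to [0, 1]; ``return_info`` additionally returns whether
    clipping occurred.  Constant series yield NaN.
    """
    params = params or HurstParams()
    x = np.asarray(x, dtype=float)
    if x.size < 4 * params.tau_max:
        raise ValueError(
            f"series of {x.size} samples too short for tau_max={params.tau_max}"
        )
    taus = params.taus
    k = np.array([np.mean(np.abs(x[t:] - x[:-t])) for t in taus])
    if np.any(k <= 0):
        h = float("nan")
        clipped = False
    else:
        h = float(np.polyfit(np.log(taus), np.log(k), 1)[0])
        clipped = False
        if clip:
            h_raw = h
            h = min(max(h, 0.0), 1.0)
            clipped = h != h_raw
    if return_info:
        return h, clipped
    return h


def spectral_entropy_from_psd(
    psd: np.ndarray, normalizer: str = "count"
) -> float:
    """Entropy of a normalized in-band power distribution.

    ``normalizer="count"`` divides by the number of bins N_f (so a flat
    distribution gives ln(N_f)/N_f); ``"log_count"`` divides by ln(N_f)
    (flat gives 1).  Zero total power yields NaN.
    """
    p = np.asarray(psd, dtype=float)
    total = p.sum()
    if total <= 0 or p.size == 0:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    n_f = p.size
    if normalizer == "count":
        return h / n_f
    if normalizer == "log_count":
        return h / math.log(n_f) if n_f > 1 else 0.0
    raise ValueError(f"unknown normalizer {normalizer!r}")


def spectral_entropy(
    x: np.ndarray, fs: float, band: BandSpec, normalizer: str = "count"
) -> float:
    """Spectral entropy of the in-band Hann periodogram of ``x``."""
    est = periodogram_hann(x, fs)
    return spectral_entropy_from_psd(est.psd[est.band_mask(band)], normalizer)


def _ordinal_patterns(x: np.ndarray, n: int, lag: int) -> np.ndarray:
    """Encode every length-n window as an integer pattern id.

    Each window ``(x_t, x_{t+lag}, ..., x_{t+(n-1)lag})`` maps to the
    permutation sorting its values in increasing order; equal values rank
    by position (stable sort).
    """
    t = x.size - (n - 1) * lag
    if t < 1:
        raise ValueError("series too short for the requested pattern order")
    idx = np.arange(t)[:, None] + lag * np.arange(n)[None, :]
    windows = x[idx]
    perms = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation row as a mixed-radix integer
    code = np.zeros(t, dtype=np.int64)
    for j in range(n):
        code = code * n + perms[:, j]
    return code


def permutation_entropy(
    x: np.ndarray,
    fs: float | None = None,
    params: PermutationParams | None = None,
    min_windows: int = 100,
) -> float:
    """Permutation entropy (natural log) of ordinal patterns of order n.

    When ``fs`` is given the series is first resampled (anti-aliased) to
    ``params.resample_fs``.  Relative frequencies are taken over all
    length-n windows.  Requires at least ``min_windows`` windows (default
    100, a sanity floor against meaningless estimates on tiny inputs).
    """
    params = params or PermutationParams()
    x = np.asarray(x, dtype=float)
    if fs is not None and fs != params.resample_fs:
        if params.resample_fs > fs:
            raise ValueError("resample_fs must not exceed the series rate")
        x = resample_series(x, fs, params.resample_fs)
    n_windows = x.size - (params.n - 1) * params.lag
    if n_windows < min_windows:
        raise ValueError(
            f"series too short: {n_windows} ordinal windows < {min_windows} required"
        )
    codes = _ordinal_patterns(x, params.n, params.lag)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def nonlinear_feature_vector(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = SUB_BANDS,
    higuchi: HiguchiParams | None = None,
    hurst: HurstParams | None = None,
    permutation: PermutationParams | None = None,
    spen_normalizer: str = "count",
    filter_order: int = 4,
) -> dict[str, float]:
    """The 16-feature nonlinear vector of one channel-epoch.

    The epoch is band-passed into each sub-band; H, HFD and SpEn are
    computed on the full-rate sub-band series and PmEn on its 64-Hz
    resampled version.  NaN markers from degenerate inputs propagate.
    """
    x = np.asarray(x, dtype=float)
    features: dict[str, float] = {}
    for band in bands:
        xb = bandpass(x, band.f_lo, band.f_hi, fs=fs, order=filter_order)
        features[f"{band.name}_H"] = generalized_hurst(xb, hurst)
        features[f"{band.name}_HFD"] = higuchi_fd(xb, higuchi)
        features[f"{band.name}_SpEn"] = spectral_entropy(xb, fs, band, spen_normalizer)
        features[f"{band.name}_PmEn"] = permutation_entropy(xb, fs, permutation)
    return features
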