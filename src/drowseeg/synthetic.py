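"""Synthetic driving-EEG sessions with labeled forced-move events.

The generator emulates the structure of a monotonous driving-simulator
session recorded with a 16-channel 10-10 montage at 512 Hz: forced lateral
moves of the vehicle occur at i.i.d. uniform intervals of 5-19 s, each event
carries a 5-level drowsiness score, and the EEG shows state-dependent band
power (drowsy periods with elevated theta/alpha and reduced beta relative
power) on top of a 1/f background.

The latent vigilance state is a two-state piecewise-constant trajectory.
Each state segment begins with a "guard" zone as long as the longest
supported analysis epoch (270 s); events inside a guard zone would have a
pre-event window straddling a state change, so they are scored at the median
level 3 and carry no binary label.  Events in the remainder of a segment
(the labeled zone) are state-pure for every epoch length up to the guard.
Awake and drowsy labeled zones alternate with lengths proportional to
``1 - drowsy_fraction`` and ``drowsy_fraction``, so the labeled-event balance
converges to ``drowsy_fraction`` without any subsampling.

The signal model is the only physiology the downstream analysis exploits:
per channel, an independent 1/f^beta Gaussian background plus, per band, a
band-passed Gaussian component whose standard deviation follows the square
root of the active state's band weight.  No eye-blink/EMG artifacts, mains
interference or electrode pops are simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .bands import ALL_BANDS, BAND_BY_NAME, BandSpec
from .recording import (
    AWAKE,
    DEFAULT_MONTAGE,
    DROWSY,
    EventTimeline,
    MultichannelRecording,
)

#: Longest analysis epoch the pipeline supports, seconds.  Event placement
#: and state-segment guards are sized so that every labeled event has a
#: state-pure pre-event window of this length after the 60-s leading
#: exclusion.
MAX_EPOCH_S = 270.0

#: Leading segment excluded from analysis (synchronization cues), seconds.
LEAD_EXCLUDE_S = 60.0

DEFAULT_AWAKE_WEIGHTS = {
    "delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 0.5,
}
DEFAULT_DROWSY_WEIGHTS = {
    "delta": 1.0, "theta": 2.0, "alpha": 2.0, "beta": 0.5, "gamma": 0.5,
}


@dataclass
class SimConfig:
    """Configuration of one synthetic driving session.

    Defaults reproduce the emulated study conditions: 16 channels at 512 Hz
    for 65 min, forced-move events at uniform 5-19 s intervals, balanced
    awake/drowsy labels, and drowsy band weights raising theta/alpha and
    lowering beta.
    """

    n_channels: int = 16
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 512.0
    duration_s: float = 3900.0
    event_interval_range_s: tuple[float, float] = (5.0, 19.0)
    state_band_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "awake": dict(DEFAULT_AWAKE_WEIGHTS),
            "drowsy": dict(DEFAULT_DROWSY_WEIGHTS),
        }
    )
    background_exponent: float = 1.0
    background_scale: float = 1.0
    component_scale: float = 1.0
    drowsy_fraction: float = 0.5
    labeled_zone_s: float = 400.0
    level3_prob: float = 0.05
    amplitude_clip: float = 25.0
    max_epoch_s: float = MAX_EPOCH_S
    #: Channels receiving the state-dependent band weights; ``None`` means
    #: all channels.  Channels outside the set always use the awake weights,
    #: which lets experiments inject an effect into one cerebral area only.
    effect_channels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= LEAD_EXCLUDE_S:
            raise ValueError("duration_s must exceed the 60-s leading exclusion")
        lo, hi = self.event_interval_range_s
        if not (0 < lo < hi):
            raise ValueError("event_interval_range_s must satisfy 0 < low < high")
        if not (0 < self.drowsy_fraction < 1):
            raise ValueError("drowsy_fraction must lie in (0, 1)")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        for state, weights in self.state_band_weights.items():
            for band, w in weights.items():
                if band not in BAND_BY_NAME:
                    raise ValueError(f"unknown band {band!r} in state {state!r}")
                if w <= 0:
                    raise ValueError(f"band weight {state}/{band} must be > 0")


def _state_segments(config: SimConfig, rng: np.random.Generator) -> list[tuple[float, float, int]]:
    """Alternating (start_s, end_s, state) segments covering the session.

    Each segment = guard (``max_epoch_s``) + labeled zone; labeled-zone
    lengths are 2 * labeled_zone_s * (class share), so labeled time — and
    hence the labeled-event balance — converges to ``drowsy_fraction``.
    """
    f = config.drowsy_fraction
    zone = {
        AWAKE: 2.0 * config.labeled_zone_s * (1.0 - f),
        DROWSY: 2.0 * config.labeled_zone_s * f,
    }
    first = int(rng.integers(0, 2))  # which state leads, so sessions differ
    segments: list[tuple[float, float, int]] = []
    t, state = 0.0, first
    while t < config.duration_s:
        end = min(t + config.max_epoch_s + zone[state], config.duration_s)
        segments.append((t, end, state))
        t, state = end, 1 - state
    return segments


def _event_levels(
    times: np.ndarray,
    segments: list[tuple[float, float, int]],
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    starts = np.array([s for s, _, _ in segments])
    states = np.array([st for _, _, st in segments])
    levels = np.empty(times.size, dtype=int)
    seg_idx = np.searchsorted(starts, times, side="right") - 1
    for i, (t, j) in enumerate(zip(times, seg_idx)):
        pure = (t - starts[j]) >= config.max_epoch_s
        if not pure or rng.uniform() < config.level3_prob:
            levels[i] = 3
        elif states[j] == AWAKE:
            levels[i] = int(rng.integers(1, 3))  # 1 or 2
        else:
            levels[i] = int(rng.integers(4, 6))  # 4 or 5
    return levels


def _shaped_background(n: int, fs: float, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^beta Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    freqs[0] = freqs[1]  # avoid the DC singularity
    spec *= freqs ** (-beta / 2.0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_component(n: int, fs: float, band: BandSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = signal.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_session(config: SimConfig) -> tuple[MultichannelRecording, EventTimeline]:
    """Generate one seeded session: recording plus event timeline.

    The same config (including seed) yields bit-identical output.  Raises
    ``ValueError`` when the duration cannot host at least one labeled event
    after the leading exclusion and the state-purity guard.
    """
    rng = np.random.default_rng(config.seed)

    # --- events: i.i.d. uniform gaps, first event after lead + guard ------
    lo, hi = config.event_interval_range_s
    t_first = LEAD_EXCLUDE_S + config.max_epoch_s
    times = []
    t = t_first + rng.uniform(lo, hi)
    while t < config.duration_s:
        times.append(t)
        t += rng.uniform(lo, hi)
    times = np.asarray(times)

    segments = _state_segments(config, rng)
    levels = (
        _event_levels(times, segments, config, rng)
        if times.size
        else np.empty(0, dtype=int)
    )
    timeline = EventTimeline(times, levels)
    if not any(l is not None for l in timeline.labels):
        raise ValueError(
            f"duration_s={config.duration_s} is too short to host a labeled "
            f"event (events start after {t_first} s and need a state-pure "
            f"window of {config.max_epoch_s} s)"
        )

    # --- per-sample state weights ----------------------------------------
    n = int(round(config.duration_s * config.fs))
    sample_t = np.arange(n) / config.fs
    starts = np.array([s for s, _, _ in segments])
    states = np.array([st for _, _, st in segments])
    state_per_sample = states[np.searchsorted(starts, sample_t, side="right") - 1]

    weights = {
        AWAKE: config.state_band_weights["awake"],
        DROWSY: config.state_band_weights["drowsy"],
    }

    # --- signal synthesis --------------------------------------------------
    effect = (
        set(config.channel_labels)
        if config.effect_channels is None
        else set(config.effect_channels)
    )
    samples = np.empty((config.n_channels, n))
    for c, label in enumerate(config.channel_labels):
        x = config.background_scale * _shaped_background(
            n, config.fs, config.background_exponent, rng
        )
        for band in ALL_BANDS:
            comp = _band_component(n, config.fs, band, rng)
            if label in effect:
                amp = np.sqrt(
                    np.where(
                        state_per_sample == DROWSY,
                        weights[DROWSY].get(band.name, 1.0),
                        weights[AWAKE].get(band.name, 1.0),
                    )
                )
            else:
                amp = np.sqrt(weights[AWAKE].get(band.name, 1.0))
            x = x + config.component_scale * amp * comp
        np.clip(x, -config.amplitude_clip, config.amplitude_clip, out=x)
        samples[c] = x

    recording = MultichannelRecording(samples, config.fs, list(config.channel_labels))
    return recording, timeline


@dataclass
class StateBandPowerSummary:
    """Per-state band-power summary from labeled pre-event windows."""

    relative: pd.DataFrame  # rows: state name; columns: band; mean relative power
    absolute: pd.DataFrame  # same layout, absolute band power
    sem_relative: pd.DataFrame
    n_windows: dict[str, int]


def state_spectral_check(
    recording: MultichannelRecording,
    timeline: EventTimeline,
    window_s: float = 30.0,
    channel: str | None = None,
) -> StateBandPowerSummary:
    """Welch band-power summary of the pre-event windows, per state.

    A validation helper: for every labeled event the ``window_s`` seconds
    before the event are spectrally estimated (Welch, 4-s segments) and the
    absolute and relative power in each canonical band is averaged per
    state.  Used to confirm that the generator's injected band-power
    structure is present in the output.
    """
    x = recording.channel(channel) if channel else recording.samples.mean(axis=0)
    fs = recording.fs
    nper = int(4 * fs)
    times, labels = timeline.labeled()
    rows: dict[int, list[np.ndarray]] = {AWAKE: [], DROWSY: []}
    abs_rows: dict[int, list[np.ndarray]] = {AWAKE: [], DROWSY: []}
    for t, lab in zip(times, labels):
        i1 = int(round((t - recording.t0) * fs))
        i0 = i1 - int(round(window_s * fs))
        if i0 < 0 or i1 > x.size:
            continue
        freqs, psd = signal.welch(x[i0:i1], fs=fs, nperseg=min(nper, i1 - i0))
        df = freqs[1] - freqs[0]
        powers = np.array(
            [psd[(freqs >= b.f_lo) & (freqs < b.f_hi)].sum() * df for b in ALL_BANDS]
        )
        total = powers.sum()
        if total <= 0:
            continue
        rows[lab].append(powers / total)
        abs_rows[lab].append(powers)

    names = [b.name for b in ALL_BANDS]
    state_names = {AWAKE: "awake", DROWSY: "drowsy"}
    rel, absolute, sem, counts = {}, {}, {}, {}
    for lab, vals in rows.items():
        key = state_names[lab]
        counts[key] = len(vals)
        if not vals:
            warnings.warn(f"no labeled {key} windows available for the check")
            rel[key] = np.full(len(names), np.nan)
            absolute[key] = np.full(len(names), np.nan)
            sem[key] = np.full(len(names), np.nan)
            continue
        arr = np.vstack(vals)
        rel[key] = arr.mean(axis=0)
        sem[key] = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        absolute[key] = np.vstack(abs_rows[lab]).mean(axis=0)

    return StateBandPowerSummary(
        relative=pd.DataFrame(rel, index=names).T,
        absolute=pd.DataFrame(absolute, index=names).T,
        sem_relative=pd.DataFrame(sem, index=names).T,
        n_windows=counts,
    )


# ---------------------------------------------------------------------------
# Reference stochastic processes for estimator calibration
# ---------------------------------------------------------------------------

def brownian_series(n: int, rng: np.random.Generator) -> np.ndarray:
    """Brownian motion as the cumulative sum of i.i.d. standard Gaussians."""
    return np.cumsum(rng.standard_normal(n))


def fractional_brownian_motion(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Brownian motion via Davies-Harte circulant embedding.

    Exact in distribution for 0 < hurst < 1 (eigenvalues of the embedded
    fGn covariance are non-negative; tiny negative rounding is clipped).
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    h2 = 2.0 * hurst
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, len 2n
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)
    m = row.size
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    fgn = np.fft.fft(np.sqrt(eig / (2.0 * m)) * w)[:n].real
    fgn *= np.sqrt(2.0)  # real part carries half the variance
    return np.cumsum(fgn)


def replace_config(config: SimConfig, **changes) -> SimConfig:
    """Return a copy of ``config`` with ``changes`` applied."""
    return replace(config, **changes)
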