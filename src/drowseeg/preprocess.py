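"""Recording I/O and the fixed preprocessing chain.

Pipeline order is fixed: read -> resample -> normalize -> exclude the
leading 60 s -> cut event-anchored epochs.  Features are computed on epochs
only.  Epoch windows are half-open ``[event - L, event)``; epochs that would
overlap the excluded leading segment are dropped (not truncated) so that
every epoch has exactly ``L * fs`` samples.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import _edf
from .recording import (
    Epoch,
    EpochingReport,
    EventTimeline,
    MultichannelRecording,
)

DEFAULT_SKIP_S = 60.0

#: Supported epoch lengths, seconds (30 s steps up to 270 s).
EPOCH_LENGTHS_S: tuple[int, ...] = (30, 60, 90, 120, 150, 180, 210, 240, 270)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt", ".tsv"):
        return "delimited"
    raise ValueError(f"cannot infer recording format from {path.name!r}")


def read_recording(path, fmt: str | None = None, fs: float | None = None) -> MultichannelRecording:
    """Read a recording from EDF or delimited text.

    Delimited files use a comma separator, a header row of channel labels
    and '.' decimals, one row per sample; their sampling rate is not stored
    in the file and must be supplied via ``fs``.  Non-finite samples raise
    an error naming the channel and sample index.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "edf":
        data, fs_read, labels = _edf.read_edf(path)
        return MultichannelRecording(data, fs_read, labels)
    if fmt == "delimited":
        if fs is None:
            raise ValueError("delimited recordings need an explicit fs")
        frame = pd.read_csv(path)
        data = frame.to_numpy(dtype=float).T
        return MultichannelRecording(data, fs, list(frame.columns))
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(recording: MultichannelRecording, path, fmt: str | None = None) -> None:
    """Write a recording to EDF (16-bit, µV) or delimited text."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "edf":
        _edf.write_edf(path, recording.samples, recording.fs, recording.channel_labels)
    elif fmt == "delimited":
        pd.DataFrame(recording.samples.T, columns=recording.channel_labels).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_timeline(path) -> EventTimeline:
    frame = pd.read_csv(path)
    return EventTimeline(frame["event_time_s"].to_numpy(), frame["level"].to_numpy())


def write_timeline(timeline: EventTimeline, path) -> None:
    labels = ["" if l is None else ("drowsy" if l else "awake") for l in timeline.labels]
    pd.DataFrame(
        {
            "event_time_s": timeline.event_times_s,
            "level": timeline.levels,
            "label": labels,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def resample_to(recording: MultichannelRecording, target_fs: float) -> MultichannelRecording:
    """Polyphase resampling to ``target_fs`` with anti-alias filtering.

    Duration is preserved within one sample period; identical rates return
    the recording unchanged.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if abs(target_fs - recording.fs) < 1e-12:
        return recording
    ratio = Fraction(target_fs / recording.fs).limit_denominator(10_000)
    out = signal.resample_poly(recording.samples, ratio.numerator, ratio.denominator, axis=1)
    return MultichannelRecording(out, target_fs, list(recording.channel_labels), recording.t0)


def resample_series(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Polyphase resampling of a single series (anti-aliased)."""
    if abs(target_fs - fs) < 1e-12:
        return np.asarray(x, dtype=float)
    ratio = Fraction(target_fs / fs).limit_denominator(10_000)
    return signal.resample_poly(np.asarray(x, dtype=float), ratio.numerator, ratio.denominator)


def normalize(recording: MultichannelRecording) -> MultichannelRecording:
    """Per-channel z-scoring over the whole recording (zero mean, unit sd)."""
    sd = recording.samples.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"constant channel(s) cannot be normalized: "
            f"{[recording.channel_labels[i] for i in flat]}"
        )
    out = (recording.samples - recording.samples.mean(axis=1, keepdims=True)) / sd
    return MultichannelRecording(out, recording.fs, list(recording.channel_labels), recording.t0)


def bandpass(
    x: np.ndarray | MultichannelRecording,
    f_lo: float,
    f_hi: float,
    fs: float | None = None,
    order: int = 4,
):
    """Zero-phase Butterworth band-pass (forward-backward, effective order 2x).

    Accepts a recording or a bare array (``fs`` required for the latter).
    Band edges must respect Nyquist.
    """
    if isinstance(x, MultichannelRecording):
        rec = x
        fs = rec.fs
        data = rec.samples
    else:
        rec = None
        if fs is None:
            raise ValueError("fs is required when filtering a bare array")
        data = np.asarray(x, dtype=float)
    if not (0 <= f_lo < f_hi < fs / 2):
        raise ValueError(
            f"band [{f_lo}, {f_hi}) must satisfy 0 <= f_lo < f_hi < fs/2 = {fs / 2}"
        )
    sos = signal.butter(order, [max(f_lo, 1e-6), f_hi], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if rec is not None:
        return MultichannelRecording(out, fs, list(rec.channel_labels), rec.t0)
    return out


def exclude_leading(recording: MultichannelRecording, skip_s: float = DEFAULT_SKIP_S) -> MultichannelRecording:
    """Drop the first ``skip_s`` seconds (synchronization cues, transients)."""
    if skip_s == 0:
        return recording
    if recording.duration_s <= skip_s:
        raise ValueError(
            f"recording of {recording.duration_s:.1f} s cannot lose its "
            f"first {skip_s} s"
        )
    n_skip = int(round(skip_s * recording.fs))
    return MultichannelRecording(
        recording.samples[:, n_skip:],
        recording.fs,
        list(recording.channel_labels),
        recording.t0 + skip_s,
    )


def epoch_before_events(
    recording: MultichannelRecording,
    timeline: EventTimeline,
    length_s: float,
    channels: list[str] | None = None,
    return_report: bool = False,
):
    """Cut one pre-event epoch per labeled event.

    Windows cover ``[event - length_s, event)``.  Events without a binary
    label (level 3) or whose window starts before the recording (after the
    leading exclusion, i.e. before ``recording.t0``) are skipped and counted
    in the report.
    """
    channels = list(channels) if channels is not None else list(recording.channel_labels)
    if not channels:
        raise ValueError("at least one channel must be selected")
    missing = set(channels) - set(recording.channel_labels)
    if missing:
        raise ValueError(f"channels not in recording: {sorted(missing)}")
    rec = recording.pick(channels)

    n_len = int(round(length_s * rec.fs))
    report = EpochingReport(n_events=timeline.n_events)
    epochs: list[Epoch] = []
    for t, label in zip(timeline.event_times_s, timeline.labels):
        if label is None:
            report.n_unlabeled += 1
            continue
        i1 = int(round((t - rec.t0) * rec.fs))
        i0 = i1 - n_len
        if i0 < 0 or i1 > rec.n_samples:
            report.n_insufficient_history += 1
            report.skipped_events.append(float(t))
            continue
        epochs.append(
            Epoch(rec.samples[:, i0:i1], rec.fs, channels, length_s, float(t), label)
        )
    report.n_epochs = len(epochs)
    if report.n_insufficient_history:
        warnings.warn(
            f"{report.n_insufficient_history} labeled event(s) lacked a full "
            f"{length_s}-s pre-event window and were skipped"
        )
    if return_report:
        return epochs, report
    return epochs


def preprocess_session(
    recording: MultichannelRecording,
    target_fs: float = 512.0,
    skip_s: float = DEFAULT_SKIP_S,
) -> MultichannelRecording:
    """The fixed chain: resample -> normalize -> exclude leading segment."""
    rec = resample_to(recording, target_fs)
    rec = normalize(rec)
    return exclude_leading(rec, skip_s)
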