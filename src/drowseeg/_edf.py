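"""Minimal EDF (European Data Format) writer.

Writes one 16-bit signal per channel with 1-second data records and a
per-channel physical scaling chosen from the data range.  Only the subset of
EDF needed to round-trip the simulator's recordings is implemented; reading
is delegated to ``mne.io.read_raw_edf`` elsewhere.
"""

from __future__ import annotations

import warnings

import numpy as np


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    channel_labels: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write a channels x time matrix to an EDF file.

    The sampling rate must be a positive integer (one data record per
    second).  Trailing samples short of a full second are dropped with a
    warning; amplitudes are quantized to 16 bits over the per-channel range.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch, n = samples.shape
    if n_ch != len(channel_labels):
        raise ValueError("one label per channel required")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    n_rec = n // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_rec * spr != n:
        warnings.warn(
            f"dropping {n - n_rec * spr} trailing samples not filling a "
            "1-s EDF record"
        )

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.abs(samples).max(axis=1), 1e-9)

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),            # patient id
        _field("Startdate X synthetic", 80),  # recording id
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),                    # record duration, seconds
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(l, 16) for l in channel_labels),
        b"".join(_field("", 80) for _ in channel_labels),
        b"".join(_field(physical_dimension, 8) for _ in channel_labels),
        b"".join(_field(f"{-p:.6g}"[:8], 8) for p in phys_max),
        b"".join(_field(f"{p:.6g}"[:8], 8) for p in phys_max),
        b"".join(_field(str(dig_min), 8) for _ in channel_labels),
        b"".join(_field(str(dig_max), 8) for _ in channel_labels),
        b"".join(_field("", 80) for _ in channel_labels),
        b"".join(_field(str(spr), 8) for _ in channel_labels),
        b"".join(_field("", 32) for _ in channel_labels),
    ])

    # quantize: digital = round(x / phys_max * dig_max)
    scale = dig_max / phys_max[:, None]
    digital = np.rint(samples[:, : n_rec * spr] * scale).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # records: for each second, each channel's spr samples contiguously
        interleaved = (
            digital.reshape(n_ch, n_rec, spr)
            .transpose(1, 0, 2)  # (record, channel, sample)
            .copy()
        )
        fh.write(interleaved.tobytes())


def edf_quantization_step(samples: np.ndarray) -> np.ndarray:
    """Per-channel amplitude resolution of a 16-bit EDF round trip."""
    phys_max = np.maximum(np.abs(np.atleast_2d(samples)).max(axis=1), 1e-9)
    return phys_max / 32767.0


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via mne; returns (samples, fs, labels).

    mne scales EDF voltages to SI units (volts); values are returned in the
    file's physical units by undoing the microvolt conversion when the
    physical dimension is uV.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    units = _physical_dimensions(path)
    for i, u in enumerate(units):
        if u.strip().lower() in ("uv", "µv"):
            data[i] *= 1e6
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def _physical_dimensions(path) -> list[str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_ch = int(head[252:256].decode("ascii"))
        sig = fh.read(256 * n_ch)
    off = (16 + 80) * n_ch
    return [
        sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii") for i in range(n_ch)
    ]
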