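"""In-memory containers for multi-channel EEG recordings, event timelines
and event-anchored epochs.

A :class:`MultichannelRecording` is a channels x samples matrix with a
sampling rate and 10-10 channel labels.  An :class:`EventTimeline` holds the
forced-move events of a driving session together with their 5-level
drowsiness scores; the median level (3) carries no binary label, levels 1-2
map to "awake" and levels 4-5 to "drowsy".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AWAKE = 0
DROWSY = 1

#: 16-electrode montage (international 10-10 system) of the driving study
#: the simulator emulates.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "Cz", "C3", "C4",
    "T7", "T8", "FT9", "FT10", "Pz", "P7", "P8", "Oz",
)


def label_from_level(level: int) -> int | None:
    """Collapse a 5-level drowsiness score to a binary label.

    Levels 1-2 ("not drowsy", "slightly drowsy") map to awake, levels 4-5
    ("very drowsy", "extremely drowsy") to drowsy.  The median level 3 is
    omitted and yields ``None``.
    """
    if level not in (1, 2, 3, 4, 5):
        raise ValueError(f"drowsiness level must be in 1..5, got {level}")
    if level <= 2:
        return AWAKE
    if level >= 4:
        return DROWSY
    return None


@dataclass
class MultichannelRecording:
    """Channels x samples EEG matrix with sampling rate and labels."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"samples has {self.samples.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels were given"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.isfinite(self.samples).all():
            ch, idx = np.argwhere(~np.isfinite(self.samples))[0]
            raise ValueError(
                f"non-finite sample in channel {self.channel_labels[ch]!r} "
                f"at sample index {idx}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D series of one channel by its 10-10 label."""
        try:
            row = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.samples[row]

    def pick(self, labels: list[str]) -> "MultichannelRecording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        rows = [self.channel_labels.index(l) for l in labels]
        return MultichannelRecording(
            self.samples[rows], self.fs, list(labels), self.t0
        )


@dataclass
class EventTimeline:
    """Ordered forced-move events with 5-level scores and binary labels."""

    event_times_s: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)
        if self.event_times_s.shape != self.levels.shape:
            raise ValueError("event_times_s and levels must align")
        if np.any(np.diff(self.event_times_s) <= 0):
            raise ValueError("event times must be strictly increasing")
        if self.levels.size and not np.isin(self.levels, [1, 2, 3, 4, 5]).all():
            raise ValueError("levels must be integers in 1..5")

    @property
    def labels(self) -> list[int | None]:
        """Binary label per event; ``None`` for unlabeled (level-3) events."""
        return [label_from_level(int(l)) for l in self.levels]

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)

    def labeled(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, labels) of events that carry a binary label."""
        lab = self.labels
        mask = np.array([l is not None for l in lab])
        return (
            self.event_times_s[mask],
            np.array([l for l in lab if l is not None], dtype=int),
        )


@dataclass
class Epoch:
    """A fixed-length pre-event window of one or more channels.

    The window is half-open ``[event_time_s - length_s, event_time_s)``:
    the event-onset sample itself is excluded.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    length_s: float
    event_time_s: float
    label: int

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        expected = int(round(self.length_s * self.fs))
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"epoch must span exactly {expected} samples "
                f"({self.length_s} s at {self.fs} Hz), got {self.samples.shape[1]}"
            )
        if self.label not in (AWAKE, DROWSY):
            raise ValueError("epoch label must be binary")

    def channel(self, label: str) -> np.ndarray:
        row = self.channel_labels.index(label)
        return self.samples[row]


@dataclass
class EpochingReport:
    """Bookkeeping of why events were kept or skipped during epoching."""

    n_events: int = 0
    n_epochs: int = 0
    n_unlabeled: int = 0
    n_insufficient_history: int = 0
    skipped_events: list[float] = field(default_factory=list)
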