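"""Epochs -> named feature tables.

Feature names are prefixed with their channel (``Fp1__alpha_power``) so
that multi-channel units (cerebral areas) concatenate per-channel features
into one row per epoch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nonlinear import nonlinear_feature_vector
from .preprocess import epoch_before_events, preprocess_session
from .recording import Epoch, EventTimeline, MultichannelRecording
from .selection import FeatureTable, drop_incomplete
from .spectral import spectral_feature_vector

FEATURE_SETS = ("S", "N", "S+N")


def epoch_feature_row(epoch: Epoch, feature_set: str = "S+N") -> dict[str, float]:
    """All requested features of one epoch, channel-prefixed."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    row: dict[str, float] = {}
    for ch in epoch.channel_labels:
        x = epoch.channel(ch)
        if feature_set in ("S", "S+N"):
            for name, value in spectral_feature_vector(x, epoch.fs).items():
                row[f"{ch}__{name}"] = value
        if feature_set in ("N", "S+N"):
            for name, value in nonlinear_feature_vector(x, epoch.fs).items():
                row[f"{ch}__{name}"] = value
    return row


def feature_table_from_epochs(
    epochs: list[Epoch], feature_set: str = "S+N"
) -> FeatureTable:
    """One feature row per epoch; epochs with any missing feature dropped."""
    if not epochs:
        raise ValueError("no epochs to extract features from")
    rows = [epoch_feature_row(e, feature_set) for e in epochs]
    labels = np.array([e.label for e in epochs], dtype=int)
    frame = pd.DataFrame(rows)
    table, _ = drop_incomplete(frame, labels)
    table.features.reset_index(drop=True, inplace=True)
    return table


def extract_feature_table(
    recording: MultichannelRecording,
    timeline: EventTimeline,
    length_s: float,
    channels: list[str] | None = None,
    feature_set: str = "S+N",
    preprocess: bool = True,
) -> FeatureTable:
    """Session -> feature table for one unit (channel set) and epoch length.

    With ``preprocess`` the fixed chain (resample to 512 Hz, per-channel
    z-scoring, 60-s leading exclusion) runs first.
    """
    rec = preprocess_session(recording) if preprocess else recording
    epochs = epoch_before_events(rec, timeline, length_s, channels)
    return feature_table_from_epochs(epochs, feature_set)


def select_feature_columns(table: FeatureTable, feature_set: str) -> FeatureTable:
    """Restrict an S+N table to the spectral or nonlinear column subset."""
    if feature_set == "S+N":
        return table
    nonlinear_stats = ("_H", "_HFD", "_SpEn", "_PmEn")
    is_nonlinear = [
        any(c.endswith(s) for s in nonlinear_stats) for c in table.feature_names
    ]
    keep = [
        c
        for c, nl in zip(table.feature_names, is_nonlinear)
        if (nl if feature_set == "N" else not nl)
    ]
    if not keep:
        raise ValueError(f"table has no {feature_set} columns")
    return FeatureTable(table.features[keep], table.labels)
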