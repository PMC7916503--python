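"""Feature tables, Fisher-score ranking and the split protocol.

The evaluation protocol mirrors a two-stage design: a stratified random
division into an optimization set (two-thirds) and a final test set
(one-third), then stratified five-fold cross-validation inside the
optimization set.  The number of ranked features kept is the smallest k
minimizing the mean squared error of classification (on 0/1-coded labels,
equal to the misclassification rate) across the five validation folds.
Ranking and selection never see the test rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit


@dataclass
class FeatureTable:
    """Named features (rows: epochs) with binary labels."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != self.labels.size:
            raise ValueError("one label per feature row required")
        if self.features.isna().any().any():
            raise ValueError(
                "feature table contains missing values; drop incomplete epochs "
                "upstream (drop_incomplete)"
            )
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size == 2 and counts.min() < 2:
            raise ValueError("need at least 2 rows per class")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features.iloc[idx], self.labels[idx])


def drop_incomplete(features: pd.DataFrame, labels: np.ndarray) -> tuple[FeatureTable, int]:
    """Drop rows with any missing feature; returns the table and the count."""
    mask = ~features.isna().any(axis=1)
    n_dropped = int((~mask).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} epoch(s) with missing features")
    return FeatureTable(features.loc[mask], np.asarray(labels)[mask.to_numpy()]), n_dropped


def fisher_score(table: FeatureTable) -> pd.DataFrame:
    """Univariate Fisher score per feature, ranked descending.

    score_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma_cj^2 over the two
    classes.  Zero within-class variance in both classes yields +inf (the
    feature separates trivially) with a warning.  Ties keep column order;
    the score is invariant to per-feature affine rescaling.
    """
    x = table.features.to_numpy(dtype=float)
    y = table.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present to rank features")
    mu = x.mean(axis=0)
    num = np.zeros(x.shape[1])
    den = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        n_c = xc.shape[0]
        num += n_c * (xc.mean(axis=0) - mu) ** 2
        den += n_c * xc.var(axis=0)  # population variance per class
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    scores = np.where((den == 0) & (num == 0), 0.0, scores)
    if np.isinf(scores).any():
        warnings.warn(
            "feature(s) with zero within-class variance ranked first: "
            f"{[table.feature_names[i] for i in np.flatnonzero(np.isinf(scores))]}"
        )
    order = np.argsort(-scores, kind="stable")
    return pd.DataFrame(
        {
            "feature": [table.feature_names[i] for i in order],
            "score": scores[order],
        }
    ).reset_index(drop=True)


@dataclass
class SplitPlan:
    """Indices of the 2/3-1/3 division and the 5 folds inside it."""

    optimization_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.optimization_idx, self.test_idx)
        if overlap.size:
            raise ValueError("optimization and test indices overlap")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def signature(self) -> tuple:
        """Hashable identity used to check that two results share a plan."""
        return (tuple(self.test_idx.tolist()), self.seed, self.n_folds)


def make_split(table: FeatureTable, seed: int, n_folds: int = 5) -> SplitPlan:
    """Stratified 2/3-1/3 split plus stratified folds, deterministic in seed."""
    n = table.n_rows
    if n < 15:
        raise ValueError(f"need at least 15 rows to split, got {n}")
    ss = np.random.SeedSequence(seed)
    seed_split, seed_folds = (int(s) for s in ss.generate_state(2) % (2**31 - 1))

    splitter = StratifiedShuffleSplit(n_splits=1, test_size=1 / 3, random_state=seed_split)
    opt_idx, test_idx = next(splitter.split(np.zeros(n), table.labels))
    opt_idx, test_idx = np.sort(opt_idx), np.sort(test_idx)

    y_opt = table.labels[opt_idx]
    classes, counts = np.unique(y_opt, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"a class has only {counts.min()} optimization rows; "
            f"{n_folds}-fold CV needs at least {n_folds}"
        )
    kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed_folds)
    folds = [
        (opt_idx[tr], opt_idx[va]) for tr, va in kf.split(np.zeros(opt_idx.size), y_opt)
    ]
    return SplitPlan(opt_idx, test_idx, folds, seed)
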