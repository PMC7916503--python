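"""Experiment orchestration: electrode/area sweeps, learning curves, reports.

``run_sweep`` evaluates every (unit, epoch length, feature set, model, seed)
cell of a sweep: epochs are cut, features extracted (areas concatenate
per-channel features), Fisher-ranked on the optimization set, the feature
count selected by five-fold CV, and the classifier scored on the held-out
third.  ``fit_learning_curve`` fits the inverse-power-law accuracy model
``a - b * n^(-c)``, whose plateau ``a`` is the extrapolated accuracy at
unlimited training size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .models import ModelSpec, run_protocol
from .pipeline import FEATURE_SETS, extract_feature_table, select_feature_columns
from .recording import EventTimeline, MultichannelRecording

#: Cerebral-area grouping of the 16-electrode montage.  Only the posterior
#: group is fully enumerated by the source montage description; frontal and
#: central membership follows the placement figure, and the fronto-temporal
#: electrodes FT9/FT10 belong to the temporal group.
DEFAULT_AREAS: dict[str, tuple[str, ...]] = {
    "F": ("Fp1", "Fp2", "Fz", "F3", "F4"),
    "C": ("Cz", "C3", "C4"),
    "T": ("T7", "T8", "FT9", "FT10"),
    "PO": ("Pz", "P7", "P8", "Oz"),
}


def area_channels(unit: str, areas: dict[str, tuple[str, ...]] | None = None) -> list[str]:
    """Channels of a unit: an area name or a single electrode label."""
    areas = areas or DEFAULT_AREAS
    if unit in areas:
        return list(areas[unit])
    return [unit]


@dataclass
class SweepConfig:
    """The grid of one experiment sweep."""

    units: tuple[str, ...]
    lengths_s: tuple[int, ...] = (30, 60, 90, 120, 150, 180)
    feature_sets: tuple[str, ...] = ("S", "N", "S+N")
    models: tuple[str, ...] = ("rf", "svm")
    seeds: tuple[int, ...] = (0,)
    areas: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_AREAS))
    k_grid: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name, values in (
            ("units", self.units),
            ("lengths_s", self.lengths_s),
            ("feature_sets", self.feature_sets),
            ("models", self.models),
            ("seeds", self.seeds),
        ):
            if not values:
                raise ValueError(f"sweep dimension {name!r} is empty")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets {sorted(unknown)}")


def run_sweep(
    session: tuple[MultichannelRecording, EventTimeline],
    sweep: SweepConfig,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Evaluate every sweep cell on one session; returns a tidy table.

    Cells that cannot be evaluated (e.g. too few epochs for the split) are
    kept as rows with NaN accuracy and the failure reason.  Results do not
    depend on the order in which cells are run: every cell derives its
    randomness from its own (model, seed) pair.
    """
    recording, timeline = session
    rows = []
    for unit in sweep.units:
        channels = area_channels(unit, sweep.areas)
        for length in sweep.lengths_s:
            try:
                full = extract_feature_table(
                    recording, timeline, length, channels, "S+N", preprocess
                )
            except ValueError as exc:
                for fs_name in sweep.feature_sets:
                    for model in sweep.models:
                        for seed in sweep.seeds:
                            rows.append(
                                _cell_row(unit, length, fs_name, model, seed, reason=str(exc))
                            )
                continue
            for fs_name in sweep.feature_sets:
                table = select_feature_columns(full, fs_name)
                n_feat = len(table.feature_names)
                if sweep.k_grid:
                    k_grid = sorted({min(k, n_feat) for k in sweep.k_grid})
                else:
                    k_grid = None
                for model in sweep.models:
                    for seed in sweep.seeds:
                        spec = ModelSpec(family=model, seed=seed)
                        try:
                            res = run_protocol(table, spec, seed, k_grid, fs_name)
                            rows.append(
                                _cell_row(
                                    unit, length, fs_name, model, seed,
                                    accuracy=res.accuracy_overall,
                                    accuracy_awake=res.accuracy_per_class["awake"],
                                    accuracy_drowsy=res.accuracy_per_class["drowsy"],
                                    k_star=res.n_features_selected,
                                    n_rows=table.n_rows,
                                )
                            )
                        except ValueError as exc:
                            rows.append(
                                _cell_row(unit, length, fs_name, model, seed, reason=str(exc))
                            )
    return pd.DataFrame(rows)


def _cell_row(unit, length, feature_set, model, seed, accuracy=np.nan,
              accuracy_awake=np.nan, accuracy_drowsy=np.nan, k_star=-1,
              n_rows=0, reason=""):
    return {
        "unit": unit,
        "length_s": length,
        "feature_set": feature_set,
        "model": model,
        "seed": seed,
        "accuracy": accuracy,
        "accuracy_awake": accuracy_awake,
        "accuracy_drowsy": accuracy_drowsy,
        "k_star": k_star,
        "n_rows": n_rows,
        "reason": reason,
    }


@dataclass
class LearningCurveFit:
    """Inverse-power-law fit ``accuracy(n) = a - b * n^(-c)``."""

    a: float
    b: float
    c: float
    residuals: np.ndarray

    @property
    def plateau(self) -> float:
        return self.a

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.a - self.b * np.asarray(n, dtype=float) ** (-self.c)


def fit_learning_curve(points: list[tuple[float, float]]) -> LearningCurveFit:
    """Nonlinear least-squares fit of the inverse power law to
    (sample size, accuracy) points.

    Needs at least 4 distinct sample sizes; raises on non-convergence with
    the optimizer's diagnostics.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, accuracy) pairs")
    n, acc = pts[:, 0], pts[:, 1]
    if np.unique(n).size < 4:
        raise ValueError(
            f"need >= 4 distinct sample sizes to fit 3 parameters, got {np.unique(n).size}"
        )

    def model(n, a, b, c):
        return a - b * n ** (-c)

    p0 = (min(float(acc.max()) + 1.0, 100.0), 30.0, 0.5)
    try:
        popt, _ = curve_fit(
            model, n, acc, p0=p0,
            bounds=([0.0, 0.0, 1e-6], [100.0, np.inf, 10.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"learning-curve fit did not converge: {exc}") from exc
    a, b, c = (float(v) for v in popt)
    return LearningCurveFit(a, b, c, residuals=acc - model(n, a, b, c))


def delta_accuracy_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per (unit, length, model, seed): accuracy(S+N) - accuracy(S)."""
    wide = results.pivot_table(
        index=["unit", "length_s", "model", "seed"],
        columns="feature_set",
        values="accuracy",
    )
    if "S" not in wide or "S+N" not in wide:
        raise ValueError("delta accuracy needs both S and S+N results")
    wide = wide.assign(delta_accuracy=wide["S+N"] - wide["S"])
    return wide.reset_index()


def report(results: pd.DataFrame, out_dir) -> list[Path]:
    """Write per-model accuracy tables, a Δaccuracy table and a seed summary.

    Each per-model table has one row per unit, one column block per epoch
    length (S, N, S+N, Δaccuracy as available) and a final ``Mean`` row,
    the arithmetic mean of each column.
    """
    if results.empty:
        raise ValueError("no results to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for model in sorted(results["model"].unique()):
        sub = results[results["model"] == model]
        wide = sub.pivot_table(
            index="unit",
            columns=["length_s", "feature_set"],
            values="accuracy",
            aggfunc="mean",
        )
        if {"S", "S+N"} <= set(sub["feature_set"].unique()):
            for length in sorted(sub["length_s"].unique()):
                if (length, "S") in wide and (length, "S+N") in wide:
                    wide[(length, "delta")] = wide[(length, "S+N")] - wide[(length, "S")]
        wide = wide.sort_index(axis=1)
        wide.loc["Mean"] = wide.mean(axis=0)
        path = out_dir / f"accuracy_{model}.csv"
        wide.to_csv(path)
        written.append(path)

    seeds = results["seed"].unique()
    grouped = results.groupby(["unit", "length_s", "feature_set", "model"])["accuracy"]
    summary = grouped.agg(["mean", "std", "count"]).reset_index()
    if seeds.size == 1:
        summary["std"] = "n/a"
    path = out_dir / "summary_across_seeds.csv"
    summary.to_csv(path, index=False)
    written.append(path)

    try:
        delta = delta_accuracy_table(results)
    except ValueError:
        pass
    else:
        path = out_dir / "delta_accuracy.csv"
        delta.to_csv(path, index=False)
        written.append(path)
    return written
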