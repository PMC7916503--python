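"""RF and SVM classifiers under the fixed evaluation protocol.

A 128-tree random forest with bagging, and an RBF-kernel SVM whose kernel
width and margin penalty come from a 30-draw log-uniform random search
scored by five-fold cross-validated misclassification MSE on the
optimization set.  Classifier implementations come from scikit-learn; the
protocol (seeding, search ranges, feature-count selection, held-out
evaluation) is defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import FeatureTable, SplitPlan

#: Log10 ranges of the SVM random search: gamma is drawn log-uniform over
#: [1e-3, 1e1] scaled by 1/n_features, C log-uniform over [1e-2, 1e3].
SVM_GAMMA_LOG10 = (-3.0, 1.0)
SVM_C_LOG10 = (-2.0, 3.0)


@dataclass(frozen=True)
class ModelSpec:
    """Family and hyperparameter policy of one classifier."""

    family: str = "rf"  # "rf" or "svm"
    n_trees: int = 128
    search_budget: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("rf", "svm"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.search_budget < 1:
            raise ValueError("search budget must be >= 1")


@dataclass
class EvaluationResult:
    """Held-out test outcome: confusion counts and accuracies in percent."""

    confusion: np.ndarray  # rows: actual (awake, drowsy); cols: classified
    accuracy_overall: float
    accuracy_per_class: dict[str, float]
    n_features_selected: int
    model_family: str
    seed: int
    feature_set: str = ""
    plan_signature: tuple = ()

    @classmethod
    def from_predictions(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        n_features_selected: int,
        model_family: str,
        seed: int,
        feature_set: str = "",
        plan_signature: tuple = (),
    ) -> "EvaluationResult":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        conf = np.zeros((2, 2), dtype=int)
        for t, p in zip(y_true, y_pred):
            conf[t, p] += 1
        per_class = {}
        for i, name in enumerate(("awake", "drowsy")):
            n_i = conf[i].sum()
            per_class[name] = 100.0 * conf[i, i] / n_i if n_i else float("nan")
        return cls(
            confusion=conf,
            accuracy_overall=100.0 * conf.trace() / conf.sum(),
            accuracy_per_class=per_class,
            n_features_selected=n_features_selected,
            model_family=model_family,
            seed=seed,
            feature_set=feature_set,
            plan_signature=plan_signature,
        )


def build_estimator(spec: ModelSpec, n_features: int, svm_params: tuple[float, float] | None = None):
    """Instantiate the scikit-learn estimator for a model spec.

    For SVM, ``svm_params = (C, gamma)`` must come from :func:`tune_svm`;
    features are standardized inside the pipeline using training-set
    statistics only.
    """
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, bootstrap=True, random_state=spec.seed
        )
    if svm_params is None:
        c, gamma = 1.0, 1.0 / n_features
    else:
        c, gamma = svm_params
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=c, gamma=gamma))


def _fold_mse(est, table: FeatureTable, cols: list[str], folds) -> float:
    # fold entries are positional row numbers into the table
    errs = []
    x = table.features[cols].to_numpy(dtype=float)
    y = table.labels
    for tr, va in folds:
        est.fit(x[tr], y[tr])
        pred = est.predict(x[va])
        errs.append(np.mean((pred - y[va]) ** 2))
    return float(np.mean(errs))


def tune_svm(
    table: FeatureTable,
    ranking: pd.DataFrame,
    plan: SplitPlan,
    spec: ModelSpec,
) -> tuple[float, float]:
    """Random search of (C, gamma) by five-fold CV MSE over all ranked features.

    Draws ``spec.search_budget`` log-uniform samples; gamma is scaled by
    1/n_features.  Deterministic in ``spec.seed``; ties keep the first draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5F4D]))
    cols = list(ranking["feature"])
    best: tuple[float, float] | None = None
    best_mse = np.inf
    for _ in range(spec.search_budget):
        c = 10.0 ** rng.uniform(*SVM_C_LOG10)
        gamma = 10.0 ** rng.uniform(*SVM_GAMMA_LOG10) / len(cols)
        est = build_estimator(spec, len(cols), (c, gamma))
        mse = _fold_mse(est, table, cols, plan.folds)
        if mse < best_mse:
            best_mse, best = mse, (c, gamma)
    assert best is not None
    return best


@dataclass
class SelectionResult:
    """Outcome of the feature-count selection."""

    k_star: int
    cv_mse: dict[int, float]
    svm_params: tuple[float, float] | None = None


def select_feature_count(
    table: FeatureTable,
    ranking: pd.DataFrame,
    plan: SplitPlan,
    spec: ModelSpec,
    k_grid: list[int] | None = None,
) -> SelectionResult:
    """Pick the number of top-ranked features by five-fold CV MSE.

    For each k in the grid the model is trained per fold on the top-k
    features and scored by the mean squared error of its 0/1 predictions
    (the misclassification rate); the smallest k attaining the minimum
    wins.  For SVM the hyperparameters are tuned once (on all ranked
    features, same folds) and reused across the grid.
    """
    n_feat = len(ranking)
    if k_grid is None:
        k_grid = list(range(1, n_feat + 1))
    if any(k < 1 or k > n_feat for k in k_grid):
        raise ValueError("k grid entries must lie in 1..n_features")

    svm_params = tune_svm(table, ranking, plan, spec) if spec.family == "svm" else None
    cv_mse: dict[int, float] = {}
    for k in k_grid:
        cols = list(ranking["feature"].iloc[:k])
        est = build_estimator(spec, k, svm_params)
        cv_mse[k] = _fold_mse(est, table, cols, plan.folds)
    best = min(cv_mse.values())
    k_star = min(k for k, v in cv_mse.items() if v == best)
    return SelectionResult(k_star, cv_mse, svm_params)


def train_and_test(
    table: FeatureTable,
    ranking: pd.DataFrame,
    k_star: int,
    plan: SplitPlan,
    spec: ModelSpec,
    svm_params: tuple[float, float] | None = None,
    feature_set: str = "",
) -> EvaluationResult:
    """Fit on the optimization set (top-k* features), score the test set."""
    cols = list(ranking["feature"].iloc[:k_star])
    x = table.features[cols].to_numpy(dtype=float)
    y = table.labels
    if np.unique(y[plan.optimization_idx]).size < 2:
        raise ValueError("optimization set is single-class; cannot train")
    est = build_estimator(spec, k_star, svm_params)
    est.fit(x[plan.optimization_idx], y[plan.optimization_idx])
    pred = est.predict(x[plan.test_idx])
    return EvaluationResult.from_predictions(
        y[plan.test_idx],
        pred,
        n_features_selected=k_star,
        model_family=spec.family,
        seed=spec.seed,
        feature_set=feature_set,
        plan_signature=plan.signature(),
    )


def run_protocol(
    table: FeatureTable,
    spec: ModelSpec,
    seed: int,
    k_grid: list[int] | None = None,
    feature_set: str = "",
) -> EvaluationResult:
    """The full per-cell protocol: split, rank, select k*, train, test.

    Ranking and hyperparameter/feature-count selection use the optimization
    rows only; the test third is touched once, by the final classifier.
    """
    from .selection import fisher_score, make_split

    plan = make_split(table, seed)
    ranking = fisher_score(table.subset(plan.optimization_idx))
    sel = select_feature_count(table, ranking, plan, spec, k_grid)
    return train_and_test(
        table, ranking, sel.k_star, plan, spec, sel.svm_params, feature_set
    )


def delta_accuracy(result_spectral: EvaluationResult, result_combined: EvaluationResult) -> float:
    """Accuracy gain (percentage points) from adding nonlinear features.

    Both results must come from the same split plan and model family.
    """
    if result_spectral.plan_signature != result_combined.plan_signature:
        raise ValueError("results come from different split plans")
    if result_spectral.model_family != result_combined.model_family:
        raise ValueError("results come from different model families")
    return result_combined.accuracy_overall - result_spectral.accuracy_overall
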