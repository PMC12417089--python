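"""Two-layer stacking ensembles for nitrogenase activity prediction.

The classification ensemble (high/low activity) and the regression ensemble
(log-scale activity) share one protocol: the training set is split 60/40;
base learners are fitted on the Training-60 part; their hold-out outputs on
the Training-40 part — positive-class probabilities for classification,
real-valued predictions for regression — form the base-learner-probability
(BLP) vector, which is appended to the Training-40 feature rows before the
meta learner is fitted. At prediction time the base layer produces the BLP
for new samples and the meta learner sees [features ‖ BLP].

Default configuration (tuned): classification uses a 5-neighbor uniform
k-NN base and a 200-tree random forest meta with decision threshold 0.55;
regression uses decision-tree and gradient-boosted-tree bases with an RBF
support-vector-regressor meta (C=1, epsilon=0.01).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import (
    BayesianRidge,
    Lasso,
    LogisticRegression,
    Ridge,
)
from sklearn.metrics import f1_score, r2_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
from xgboost import XGBClassifier, XGBRegressor

from .data_model import SplitSpec, logger, stratified_split_indices

MODEL_FORMAT_VERSION = 1

# family name -> (constructor, accepts random_state)
_CLASSIFIERS = {
    "knn": (KNeighborsClassifier, False),
    "random_forest": (RandomForestClassifier, True),
    "xgb": (XGBClassifier, True),
    "svm": (lambda **kw: SVC(probability=True, **kw), True),
    "logistic_regression": (LogisticRegression, True),
    "decision_tree": (DecisionTreeClassifier, True),
    "gradient_boosting": (GradientBoostingClassifier, True),
    "adaboost": (AdaBoostClassifier, True),
    "mlp": (MLPClassifier, True),
    "qda": (QuadraticDiscriminantAnalysis, False),
}
_REGRESSORS = {
    "xgbr": (XGBRegressor, True),
    "knn_regressor": (KNeighborsRegressor, False),
    "gradient_boosting_regressor": (GradientBoostingRegressor, True),
    "random_forest_regressor": (RandomForestRegressor, True),
    "svr": (SVR, False),
    "lasso": (Lasso, True),
    "ridge": (Ridge, True),
    "bayesian_ridge": (BayesianRidge, False),
    "decision_tree_regressor": (DecisionTreeRegressor, True),
}


_SCALE_SENSITIVE = frozenset(
    {
        "knn", "svm", "logistic_regression", "mlp",
        "knn_regressor", "svr", "lasso", "ridge", "bayesian_ridge",
    }
)


@dataclass(frozen=True)
class LearnerSpec:
    """A learner family plus hyperparameters and a seed."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _CLASSIFIERS and self.family not in _REGRESSORS:
            raise ValueError(f"unknown learner family {self.family!r}")

    @property
    def task(self) -> str:
        return "classification" if self.family in _CLASSIFIERS else "regression"

    def build(self):
        ctor, seeded = (_CLASSIFIERS.get(self.family) or _REGRESSORS[self.family])
        kwargs = dict(self.params)
        if seeded:
            kwargs.setdefault("random_state", self.seed)
        est = ctor(**kwargs)
        # distance/margin-based learners need standardized inputs: the raw
        # blocks mix unit frequencies with base-pair distances in the 1e3-1e4
        # range, which would otherwise dominate every kernel and neighborhood
        if self.family in _SCALE_SENSITIVE:
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        return est


# Tuned default configurations and the grids they were searched over.
DEFAULT_CLS_BASE = LearnerSpec("knn", {"n_neighbors": 5, "weights": "uniform"})
DEFAULT_CLS_META = LearnerSpec(
    "random_forest",
    {
        "n_estimators": 200,
        "max_depth": None,
        "min_samples_split": 5,
        "min_samples_leaf": 1,
        "max_features": "log2",
        "bootstrap": True,
    },
)
DEFAULT_THRESHOLD = 0.55
DEFAULT_REG_BASES = (
    LearnerSpec(
        "decision_tree_regressor",
        {
            "max_depth": 5,
            "splitter": "random",
            "min_samples_split": 10,
            "min_samples_leaf": 1,
            "max_features": "sqrt",
        },
    ),
    LearnerSpec(
        "xgbr",
        {"max_depth": 5, "learning_rate": 0.01, "n_estimators": 200, "gamma": 0},
    ),
)
DEFAULT_REG_META = LearnerSpec(
    "svr", {"kernel": "rbf", "C": 1, "epsilon": 0.01, "gamma": "scale"}
)

KNN_GRID = {
    "n_neighbors": [3, 5, 7],
    "weights": ["uniform", "distance"],
    "algorithm": ["auto", "ball_tree", "kd_tree", "brute"],
    "leaf_size": [30, 50, 100],
}
RF_GRID = {
    "n_estimators": [100, 200],
    "max_depth": [None, 10],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 2],
    "max_features": ["sqrt", "log2", None],
    "bootstrap": [True, False],
}
THRESHOLD_GRID = [0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7]
DTR_GRID = {
    "max_depth": [None, 5, 10, 20],
    "splitter": ["best", "random"],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 4],
    "max_features": ["sqrt", "log2", None],
}
XGBR_GRID = {
    "max_depth": [3, 5, 10],
    "learning_rate": [0.01, 0.1, 0.2],
    "n_estimators": [100, 200],
    "gamma": [0, 1, 5],
}
SVR_GRID = {
    "kernel": ["rbf", "linear"],
    "C": [0.1, 1, 10],
    "epsilon": [0.01, 0.1, 1],
    "gamma": ["scale", "auto"],
}


@dataclass
class StackingModel:
    """A fitted two-layer stacking ensemble."""

    task: str
    group_names: tuple[str, ...]
    base_specs: tuple[LearnerSpec, ...]
    base_models: list
    meta_spec: LearnerSpec
    meta_model: object
    threshold: float = DEFAULT_THRESHOLD
    metadata: dict = field(default_factory=dict)


def _base_outputs(base_models: list, X: np.ndarray, task: str) -> np.ndarray:
    """BLP matrix: one column per base learner."""
    cols = []
    for m in base_models:
        if task == "classification":
            cols.append(m.predict_proba(X)[:, 1])
        else:
            cols.append(m.predict(X))
    return np.column_stack(cols)


def fit_stacking(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    base_specs=None,
    meta_spec: LearnerSpec | None = None,
    split: SplitSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    group_names: tuple[str, ...] = (),
    X_base: np.ndarray | None = None,
) -> StackingModel:
    """Fit the two-layer ensemble via the Training-60/Training-40 protocol.

    ``X_base`` optionally gives the base layer its own feature matrix
    (row-aligned with ``X``); by default both layers see ``X``. Prediction
    then requires the same two matrices (see :func:`predict_proba`).
    """
    X = np.asarray(X, dtype=float)
    Xb = X if X_base is None else np.asarray(X_base, dtype=float)
    if len(Xb) != len(X):
        raise ValueError("X_base must be row-aligned with X")
    y = np.asarray(y, dtype=float)
    if len(X) < 20:
        raise ValueError(f"need >= 20 samples to build a stacking ensemble, got {len(X)}")
    if task == "classification":
        base_specs = tuple(base_specs) if base_specs else (DEFAULT_CLS_BASE,)
        meta_spec = meta_spec or DEFAULT_CLS_META
        if not 0 < threshold < 1:
            raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    elif task == "regression":
        base_specs = tuple(base_specs) if base_specs else DEFAULT_REG_BASES
        meta_spec = meta_spec or DEFAULT_REG_META
    else:
        raise ValueError(f"unknown task {task!r}")

    split = split or SplitSpec(0.6, stratified=(task == "classification"))
    strat_labels = y.astype(int) if task == "classification" else np.zeros(len(y), int)
    if task == "classification" and len(np.unique(strat_labels)) < 2:
        raise ValueError("classification requires both classes in the training data")
    idx60, idx40 = stratified_split_indices(strat_labels, split)

    base_models = []
    for spec in base_specs:
        model = spec.build()
        model.fit(Xb[idx60], y[idx60].astype(int) if task == "classification" else y[idx60])
        base_models.append(model)

    blp40 = _base_outputs(base_models, Xb[idx40], task)
    meta_X = np.hstack([X[idx40], blp40])
    meta_model = meta_spec.build()
    meta_model.fit(
        meta_X, y[idx40].astype(int) if task == "classification" else y[idx40]
    )

    return StackingModel(
        task=task,
        group_names=tuple(group_names),
        base_specs=base_specs,
        base_models=base_models,
        meta_spec=meta_spec,
        meta_model=meta_model,
        threshold=threshold,
        metadata={
            "split": {"fraction": split.fraction, "seed": split.seed},
            "n_train60": int(len(idx60)),
            "n_train40": int(len(idx40)),
            "separate_base_features": X_base is not None,
        },
    )


def _meta_input(
    model: StackingModel, X: np.ndarray, X_base: np.ndarray | None
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if model.metadata.get("separate_base_features") and X_base is None:
        raise ValueError("model was fitted with separate base features; pass X_base")
    Xb = X if X_base is None else np.asarray(X_base, dtype=float)
    blp = _base_outputs(model.base_models, Xb, model.task)
    return np.hstack([X, blp])


def predict_proba(
    model: StackingModel, X: np.ndarray, X_base: np.ndarray | None = None
) -> np.ndarray:
    """Meta-learner positive-class probability per sample (classification)."""
    if model.task != "classification":
        raise ValueError("predict_proba is defined for classification models")
    return model.meta_model.predict_proba(_meta_input(model, X, X_base))[:, 1]


def predict_label(
    model: StackingModel,
    X: np.ndarray,
    threshold: float | None = None,
    X_base: np.ndarray | None = None,
) -> np.ndarray:
    """Binary label: 1 iff probability >= threshold (inclusive)."""
    thr = model.threshold if threshold is None else threshold
    if not 0 < thr < 1:
        raise ValueError(f"threshold must be in (0, 1), got {thr}")
    return (predict_proba(model, X, X_base) >= thr).astype(int)


def predict_value(
    model: StackingModel, X: np.ndarray, X_base: np.ndarray | None = None
) -> np.ndarray:
    """Regression prediction on the log-activity scale."""
    if model.task != "regression":
        raise ValueError("predict_value is defined for regression models")
    return model.meta_model.predict(_meta_input(model, X, X_base))


def tune_threshold(probs: np.ndarray, y: np.ndarray, grid=None) -> float:
    """Pick the F1-maximizing decision threshold from a grid (tie: first)."""
    grid = list(grid) if grid is not None else list(THRESHOLD_GRID)
    best_thr, best_f1 = grid[0], -1.0
    for thr in grid:
        score = f1_score(y, (np.asarray(probs) >= thr).astype(int), zero_division=0)
        if score > best_f1:
            best_thr, best_f1 = thr, score
    return best_thr


def grid_search(
    family: str,
    grid: dict[str, list],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    metric: str | None = None,
    seed: int = 0,
) -> tuple[LearnerSpec, list[tuple[dict, float]]]:
    """Exhaustive grid search with k-fold CV; tie broken by grid order.

    Grid cells are enumerated as the Cartesian product of the value lists in
    declared key order. A cell that fails to fit is scored -inf and logged.
    Returns the winning spec and the full (params, score) table.
    """
    if not grid or any(not v for v in grid.values()):
        raise ValueError("grid must be non-empty")
    spec0 = LearnerSpec(family, seed=seed)
    task = spec0.task
    metric = metric or ("f1" if task == "classification" else "r2")
    if task == "classification":
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        y_fit = np.asarray(y).astype(int)
    else:
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        y_fit = np.asarray(y, dtype=float)
    scorer = f1_score if metric == "f1" else r2_score

    keys = list(grid)
    results: list[tuple[dict, float]] = []
    best: tuple[dict, float] | None = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        try:
            fold_scores = []
            for tr, te in cv.split(X, y_fit):
                est = LearnerSpec(family, params, seed).build()
                est.fit(X[tr], y_fit[tr])
                pred = est.predict(X[te])
                fold_scores.append(
                    scorer(y_fit[te], pred, zero_division=0)
                    if metric == "f1"
                    else scorer(y_fit[te], pred)
                )
            score = float(np.mean(fold_scores))
        except Exception as exc:  # noqa: BLE001 - any fit failure scores worst
            logger.warning("grid cell %s failed: %s", params, exc)
            score = float("-inf")
        results.append((params, score))
        if best is None or score > best[1]:
            best = (params, score)
    return LearnerSpec(family, best[0], seed), results


def save_model(model: StackingModel, path: str | Path) -> None:
    """Persist a fitted ensemble as a versioned joblib archive + JSON sidecar."""
    path = Path(path)
    payload = {"format_version": MODEL_FORMAT_VERSION, "model": model}
    joblib.dump(payload, path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "task": model.task,
        "group_names": list(model.group_names),
        "base_learners": [s.family for s in model.base_specs],
        "meta_learner": model.meta_spec.family,
        "threshold": model.threshold,
        **model.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> StackingModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model archive {path} does not exist")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"corrupt model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not an nfembed model archive")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
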