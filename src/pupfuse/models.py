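"""Classifier families behind a uniform probability-score contract.

Three families are supported: random forest (the workhorse), RBF-kernel
SVM with an exhaustive (C, gamma) grid search over 2^-7..2^8 by 10-fold
cross-validated accuracy, and k-nearest neighbors. Every trained model
exposes scores in [0, 1] (higher = more pupylation-like): the fraction of
trees voting positive for RF, a sigmoid-calibrated probability for SVM,
and the positive-neighbor fraction for KNN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoders import FeatureMatrix

logger = logging.getLogger(__name__)

SVM_GRID = [2.0 ** p for p in range(-7, 9)]  # 2^-7 .. 2^8


@dataclass
class ModelSpec:
    family: str  # RF | SVM | KNN
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("RF", "SVM", "KNN"):
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    encoding: str
    estimator: Any
    n_features: int
    selected_features: np.ndarray | None = None
    feature_names: list[str] | None = None


@dataclass
class ModelScores:
    scores: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)


def _check_trainable(matrix: FeatureMatrix) -> None:
    if matrix.labels is None:
        raise ValueError("training requires labels")
    counts = np.bincount(matrix.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("training needs at least 2 samples per class")


def _svm_grid_search(X: np.ndarray, y: np.ndarray, seed: int,
                     grid=SVM_GRID, folds: int = 10) -> tuple[float, float]:
    """Pick (C, gamma) maximizing CV accuracy; ties -> smallest C, then gamma."""
    folds = min(folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (-np.inf, None, None)
    for C in grid:          # ascending, so first strict max = smallest C/gamma
        for gamma in grid:
            acc = 0.0
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(X[tr], y[tr])
                acc += (clf.predict(X[te]) == y[te]).mean()
            acc /= len(splits)
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2]


def train(spec: ModelSpec, matrix: FeatureMatrix) -> TrainedModel:
    """Fit one classifier on a labeled feature matrix.

    RF: ``tree_count`` trees (default 500) under the spec seed.
    SVM: features standardized with training statistics; (C, gamma) from
    the spec when given, otherwise chosen by the 10-fold grid search.
    KNN: ``n_neighbors`` (default 5).
    """
    _check_trainable(matrix)
    hp = spec.hyperparameters
    if spec.family == "RF":
        est = RandomForestClassifier(
            n_estimators=hp.get("tree_count", 500), random_state=spec.seed, n_jobs=1
        )
        est.fit(matrix.X, matrix.labels)
    elif spec.family == "SVM":
        scaler = StandardScaler()
        Xs = scaler.fit_transform(matrix.X)
        if np.all(scaler.scale_ == 1.0) and np.all(matrix.X.std(axis=0) == 0):
            raise ValueError("zero-variance feature matrix: SVM cannot be scaled")
        C, gamma = hp.get("C"), hp.get("gamma")
        if C is None or gamma is None:
            C, gamma = _svm_grid_search(Xs, matrix.labels, spec.seed,
                                        grid=hp.get("grid", SVM_GRID),
                                        folds=hp.get("grid_folds", 10))
            logger.info("SVM grid search chose C=%g gamma=%g", C, gamma)
        svc = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
                  random_state=spec.seed)
        est = Pipeline([("scale", scaler), ("svc", svc)])
        # scaler already fit; fit the pipeline end-to-end for consistency
        est.fit(matrix.X, matrix.labels)
        spec = ModelSpec("SVM", {**hp, "C": C, "gamma": gamma}, spec.seed)
    else:  # KNN
        est = KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
        est.fit(matrix.X, matrix.labels)
    return TrainedModel(spec=spec, encoding=matrix.encoding, estimator=est,
                        n_features=matrix.n_features, feature_names=matrix.names)


def predict_scores(model: TrainedModel, matrix: FeatureMatrix) -> ModelScores:
    """Probability-like scores in [0, 1] for each row of the matrix."""
    if matrix.n_features != model.n_features:
        raise ValueError(
            f"matrix has {matrix.n_features} features, model expects {model.n_features}"
        )
    proba = model.estimator.predict_proba(matrix.X)
    classes = list(getattr(model.estimator, "classes_",
                           model.estimator[-1].classes_ if isinstance(model.estimator, Pipeline)
                           else [0, 1]))
    pos_col = classes.index(1)
    return ModelScores(np.clip(proba[:, pos_col], 0.0, 1.0), labels=matrix.labels)
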