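"""Evaluation: confusion metrics, ROC/PR curves, specificity-controlled
thresholds, stratified 10-fold cross-validation and fold-wise AUC tests.

Metric conventions: a prediction is positive when score >= threshold;
metrics with a zero denominator are reported as NaN ("undefined", never
coerced to 0), except MCC which takes the standard value 0 when any
factor under the root vanishes. ROC AUC uses the trapezoid rule; the
precision-recall area uses the step (rectangle) rule to avoid optimistic
interpolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .encoders import FeatureMatrix
from .feature_selection import chi2_scores, select_top_k
from .fusion import FusionWeights, fuse_scores, optimize_weights
from .models import ModelScores, ModelSpec, predict_scores, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    sens: float
    spec: float
    acc: float
    mcc: float
    precision: float
    recall: float


@dataclass
class CurvePoints:
    x: np.ndarray
    y: np.ndarray
    auc: float


def confusion_at_threshold(scores: ModelScores, threshold: float) -> ConfusionCounts:
    """Counts under the rule: predicted positive iff score >= threshold."""
    if scores.labels is None:
        raise ValueError("labels required")
    pred = scores.scores >= threshold
    pos = scores.labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)), FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, accuracy, MCC, precision, recall.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)), taken as 0
    when any factor is 0; other zero-denominator metrics are NaN.
    """
    sens = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP)
    acc = _ratio(c.TP + c.TN, c.n)
    prec = _ratio(c.TP, c.TP + c.FP)
    denom = (c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    mcc = 0.0 if denom == 0 else (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricSet(sens=sens, spec=spec, acc=acc, mcc=mcc, precision=prec, recall=sens)


def roc_points(scores: ModelScores) -> CurvePoints:
    """ROC curve (FPR, TPR) over all distinct score thresholds; trapezoid AUC."""
    if scores.labels is None or len(np.unique(scores.labels)) < 2:
        raise ValueError("ROC needs labels from both classes")
    fpr, tpr, _ = _sk_roc_curve(scores.labels, scores.scores)
    return CurvePoints(x=fpr, y=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def pr_points(scores: ModelScores) -> CurvePoints:
    """Precision-recall curve; area by the step rule (no interpolation)."""
    if scores.labels is None or len(np.unique(scores.labels)) < 2:
        raise ValueError("PR needs labels from both classes")
    prec, rec, _ = precision_recall_curve(scores.labels, scores.scores)
    # arrays come recall-descending; step rule = sum of dR * P at each step
    area = float(-np.sum(np.diff(rec) * prec[:-1]))
    return CurvePoints(x=rec[::-1], y=prec[::-1], auc=area)


def threshold_at_specificity(scores: ModelScores, target_spec: float) -> float:
    """Smallest threshold whose specificity is >= target.

    Candidate thresholds are the distinct scores, plus one just above the
    maximum (all-negative prediction, specificity 1) when no candidate
    reaches the target.
    """
    if scores.labels is None:
        raise ValueError("labels required")
    neg = scores.scores[scores.labels == 0]
    if len(neg) == 0:
        raise ValueError("needs at least one negative sample")
    for t in np.unique(scores.scores):
        spec = np.mean(neg < t)  # rule: >= t predicted positive
        if spec >= target_spec:
            return float(t)
    t = float(scores.scores.max()) + 1e-9
    logger.warning("target specificity %.3f unattainable at any score threshold; "
                   "using %.6g (all-negative)", target_spec, t)
    return t


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class CVReport:
    fold_assignment: np.ndarray          # fold index per sample
    oof_scores: ModelScores              # pooled out-of-fold scores
    fold_aucs: list[float]
    pooled_auc: float
    pooled_auprc: float
    config: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        return config_hash(self.config)

    def metrics_at(self, threshold: float) -> MetricSet:
        return metrics(confusion_at_threshold(self.oof_scores, threshold))


def kfold_cv(matrix: FeatureMatrix, model_spec: ModelSpec, folds: int = 10,
             seed: int = 0, select_k: int | None = None,
             selection_scope: str = "fold") -> CVReport:
    """Stratified seeded k-fold CV for a single encoding.

    Feature selection (when ``select_k`` is given) and training happen on
    the training split of each fold only; out-of-fold scores are pooled
    for the curves and the per-fold AUCs retained for t-tests.
    """
    if matrix.labels is None:
        raise ValueError("matrix must carry labels")
    y = matrix.labels
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError(f"each class needs at least {folds} samples for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.full(len(y), -1, dtype=int)
    oof = np.zeros(len(y))
    fold_aucs: list[float] = []
    whole_ranking = None
    if select_k is not None and selection_scope == "whole":
        whole_ranking = select_top_k(chi2_scores(matrix.X, y), matrix.n_features).ranking

    for fold, (tr, te) in enumerate(skf.split(matrix.X, y)):
        assignment[te] = fold
        cols = slice(None)
        names = matrix.names
        if select_k is not None:
            ranking = (whole_ranking if whole_ranking is not None
                       else select_top_k(chi2_scores(matrix.X[tr], y[tr]),
                                         matrix.n_features).ranking)
            cols = ranking[:select_k]
            names = [matrix.names[c] for c in cols]
        sub = FeatureMatrix(matrix.encoding, matrix.X[tr][:, cols] if select_k else matrix.X[tr],
                            names, y[tr])
        model = train(model_spec, sub)
        test = FeatureMatrix(matrix.encoding, matrix.X[te][:, cols] if select_k else matrix.X[te],
                             names, y[te])
        fold_scores = predict_scores(model, test)
        oof[te] = fold_scores.scores
        fold_aucs.append(roc_points(fold_scores).auc)

    pooled = ModelScores(oof, labels=y)
    cfg = {"encoding": matrix.encoding, "family": model_spec.family,
           "hyperparameters": model_spec.hyperparameters, "seed": seed,
           "folds": folds, "select_k": select_k, "selection_scope": selection_scope}
    return CVReport(fold_assignment=assignment, oof_scores=pooled,
                    fold_aucs=fold_aucs, pooled_auc=roc_points(pooled).auc,
                    pooled_auprc=pr_points(pooled).auc, config=cfg)


@dataclass
class FusedCVReport:
    per_encoding: dict[str, CVReport]
    weights: FusionWeights
    fused: CVReport


def fused_cv(matrices: Mapping[str, FeatureMatrix], model_spec: ModelSpec,
             folds: int = 10, seed: int = 0,
             select_k: Mapping[str, int] | None = None,
             weight_step: float = 0.1,
             selection_scope: str = "fold") -> FusedCVReport:
    """Cross-validate every encoding, fuse out-of-fold scores, report both.

    All encodings share the same fold assignment (same seed and labels),
    the fusion weights are optimized on the pooled out-of-fold scores,
    and per-fold fused AUCs are computed on the shared folds.
    """
    reports = {
        enc: kfold_cv(m, model_spec, folds=folds, seed=seed,
                      select_k=(select_k or {}).get(enc), selection_scope=selection_scope)
        for enc, m in matrices.items()
    }
    first = next(iter(reports.values()))
    labels = first.oof_scores.labels
    per_scores = {enc: r.oof_scores for enc, r in reports.items()}
    weights = optimize_weights(per_scores, labels, step=weight_step)
    fused_scores = fuse_scores(per_scores, weights)
    assignment = first.fold_assignment
    fold_aucs = []
    for fold in range(folds):
        m = assignment == fold
        fold_aucs.append(roc_points(
            ModelScores(fused_scores.scores[m], labels=labels[m])).auc)
    fused_report = CVReport(
        fold_assignment=assignment, oof_scores=fused_scores, fold_aucs=fold_aucs,
        pooled_auc=roc_points(fused_scores).auc,
        pooled_auprc=pr_points(fused_scores).auc,
        config={"fusion": True, "weights": weights.weights, "seed": seed,
                "folds": folds, "family": model_spec.family},
    )
    return FusedCVReport(per_encoding=reports, weights=weights, fused=fused_report)


def compare_auc_ttest(fold_aucs_a, fold_aucs_b) -> tuple[float, float]:
    """Welch two-sample t-test on per-fold AUCs; returns (t, two-sided p).

    Identical inputs give (0, 1); zero variance in both groups with
    different means is an error.
    """
    a = np.asarray(fold_aucs_a, dtype=float)
    b = np.asarray(fold_aucs_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 folds per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def write_report(report: CVReport, path) -> None:
    """Persist a CV report as JSON (metrics at 0.5 plus curves inline)."""
    m = report.metrics_at(0.5)
    payload = {
        "config": report.config,
        "config_hash": report.hash,
        "pooled_auc": report.pooled_auc,
        "pooled_auprc": report.pooled_auprc,
        "fold_aucs": report.fold_aucs,
        "metrics_at_0.5": {k: (None if isinstance(v, float) and math.isnan(v) else v)
                           for k, v in vars(m).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
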