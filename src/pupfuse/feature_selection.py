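"""Chi-squared feature ranking against the class label.

Each feature is discretized into at most ``bins`` equal-width bins over
its observed range, and the Pearson chi-squared statistic of the
bin-by-class contingency table is computed (zero-margin rows dropped;
constant features score 0). Ranking is deterministic: score descending,
ties broken by ascending feature index. The top-k sweep evaluates
cross-validated AUC over a grid of k values with selection performed
inside each training fold, so no information leaks from validation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .encoders import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = tuple(range(20, 501, 20))


@dataclass
class SelectionResult:
    encoding: str
    scores: np.ndarray
    ranking: np.ndarray  # feature indices, best first
    chosen_k: int
    chosen_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if sorted(self.ranking) != list(range(len(self.scores))):
            raise ValueError("ranking must be a permutation of all feature indices")
        if not 1 <= self.chosen_k <= len(self.scores):
            raise ValueError(f"chosen_k={self.chosen_k} out of range")
        self.chosen_indices = self.ranking[: self.chosen_k]


def chi2_scores(X: np.ndarray, y: np.ndarray, bins: int = 10) -> np.ndarray:
    """Per-feature chi-squared statistic of discretized feature vs class.

    Equal-width binning over each feature's observed range; a constant
    feature occupies a single bin and scores 0. Bins with zero total
    count are dropped before the statistic is formed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("chi2_scores needs samples from both classes")
    n = len(y)
    class_masks = [y == c for c in classes]
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if lo == hi:
            continue
        edges = np.linspace(lo, hi, bins + 1)
        idx = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, bins - 1)
        table = np.stack([np.bincount(idx[m], minlength=bins) for m in class_masks],
                         axis=1)  # (bins, classes)
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2:
            continue
        row_tot = table.sum(axis=1, keepdims=True)
        col_tot = table.sum(axis=0, keepdims=True)
        expected = row_tot * col_tot / n
        out[j] = ((table - expected) ** 2 / expected).sum()
    return out


def select_top_k(scores: np.ndarray, k: int, encoding: str = "") -> SelectionResult:
    """Deterministic top-k by score; ties broken by ascending feature index."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= len(scores):
        raise ValueError(f"k={k} out of range for {len(scores)} features")
    # stable sort on -score keeps ascending-index order within ties
    ranking = np.argsort(-scores, kind="stable")
    return SelectionResult(encoding=encoding, scores=scores, ranking=ranking, chosen_k=k)


def sweep_top_k(matrix: FeatureMatrix, model_spec, grid=DEFAULT_K_GRID,
                cv_folds: int = 10, seed: int = 0, bins: int = 10,
                selection_scope: str = "fold") -> tuple[int, dict[int, float]]:
    """Cross-validated AUC over a grid of top-k sizes.

    Returns (best_k, {k: mean AUC}); best_k is the argmax, smallest k on
    ties. With ``selection_scope="fold"`` (the default) the chi-squared
    ranking is recomputed on each training fold; ``"whole"`` ranks once on
    the full data, which replicates the common but leaky practice.
    """
    from .models import predict_scores, train  # local import to avoid a cycle

    if matrix.labels is None:
        raise ValueError("matrix must carry labels")
    usable = [k for k in grid if k <= matrix.n_features]
    skipped = [k for k in grid if k > matrix.n_features]
    if skipped:
        logger.warning("skipping grid values above feature count: %s", skipped)
    if not usable:
        raise ValueError("no usable k values in grid")

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    if selection_scope == "whole":
        whole_ranking = select_top_k(
            chi2_scores(matrix.X, matrix.labels, bins), len(matrix.names)
        ).ranking
    elif selection_scope != "fold":
        raise ValueError("selection_scope must be 'fold' or 'whole'")

    auc_sums = {k: 0.0 for k in usable}
    for train_idx, test_idx in skf.split(matrix.X, matrix.labels):
        y_tr, y_te = matrix.labels[train_idx], matrix.labels[test_idx]
        if selection_scope == "fold":
            ranking = select_top_k(
                chi2_scores(matrix.X[train_idx], y_tr, bins), matrix.n_features
            ).ranking
        else:
            ranking = whole_ranking
        for k in usable:
            cols = ranking[:k]
            sub = FeatureMatrix(matrix.encoding, matrix.X[train_idx][:, cols],
                                [matrix.names[c] for c in cols], y_tr)
            model = train(model_spec, sub)
            test = FeatureMatrix(matrix.encoding, matrix.X[test_idx][:, cols],
                                 sub.names, y_te)
            auc_sums[k] += roc_auc_score(y_te, predict_scores(model, test).scores)
    mean_auc = {k: auc_sums[k] / cv_folds for k in usable}
    best_k = min(usable, key=lambda k: (-mean_auc[k], k))
    return best_k, mean_auc


def write_selection(result: SelectionResult, names: list[str], path) -> None:
    """Persist a ranking as TSV: rank, feature name, chi-squared score."""
    with open(path, "w") as fh:
        fh.write("rank\tfeature\tchi2\n")
        for rank, idx in enumerate(result.ranking, start=1):
            fh.write(f"{rank}\t{names[idx]}\t{result.scores[idx]:.6g}\n")
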