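"""Weighted linear fusion of per-encoding classifier scores.

The fused score of a sample is the convex combination

    Cl = sum_i  w_i * s_i,      sum_i w_i = 1,  w_i >= 0,

where s_i is the probability score from the model trained on encoding i.
Weights are found by exhaustively enumerating the simplex grid at a fixed
step (1001 candidates for five encodings at step 0.1) and keeping the
vector that maximizes ROC AUC of the fused scores on pooled out-of-fold
predictions. Ties go to the lexicographically smallest vector in the
canonical encoding order, so the search is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .encoders import ENCODINGS
from .models import ModelScores, TrainedModel


@dataclass
class FusionWeights:
    weights: dict[str, float]
    resolution: float = 0.1

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()))
        if np.any(vals < 0):
            raise ValueError("weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {vals.sum()}")


@dataclass
class FusionModel:
    models: dict[str, TrainedModel]
    weights: FusionWeights
    threshold: float | None = None

    def __post_init__(self) -> None:
        if set(self.models) != set(self.weights.weights):
            raise ValueError("weight keys must equal the model-encoding set")


#: Canonical default weight vector (AAI, Binary, TPC, CKSAAP, pbCKSAAP).
DEFAULT_WEIGHTS = FusionWeights(
    {"AAI": 0.1, "Binary": 0.1, "TPC": 0.2, "CKSAAP": 0.3, "pbCKSAAP": 0.3}
)


def simplex_grid(n: int, step: float) -> Iterator[tuple[float, ...]]:
    """All nonnegative n-vectors on the step-grid summing to 1, in
    lexicographically ascending order."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"step {step} must divide 1 evenly")

    def rec(remaining: int, parts: int):
        if parts == 1:
            yield (remaining,)
            return
        for first in range(remaining + 1):
            for rest in rec(remaining - first, parts - 1):
                yield (first,) + rest

    for units in rec(m, n):
        yield tuple(u / m for u in units)


def simplex_grid_size(n: int, step: float) -> int:
    """C(m + n - 1, n - 1) candidate vectors for m = 1/step (stars and bars)."""
    from math import comb

    m = round(1.0 / step)
    return comb(m + n - 1, n - 1)


def fuse_scores(per_encoding_scores: Mapping[str, ModelScores],
                weights: FusionWeights) -> ModelScores:
    """Per-sample weighted sum of the encoding scores (Cl)."""
    if set(per_encoding_scores) != set(weights.weights):
        raise ValueError("score keys must match weight keys")
    lengths = {len(s.scores) for s in per_encoding_scores.values()}
    if len(lengths) != 1:
        raise ValueError("all score vectors must have the same length")
    fused = np.zeros(lengths.pop())
    labels = None
    for enc, s in per_encoding_scores.items():
        fused += weights.weights[enc] * s.scores
        if s.labels is not None:
            labels = s.labels
    return ModelScores(np.clip(fused, 0.0, 1.0), labels=labels)


def optimize_weights(per_encoding_scores: Mapping[str, ModelScores],
                     labels: np.ndarray, step: float = 0.1,
                     order: Sequence[str] | None = None) -> FusionWeights:
    """Exhaustive simplex-grid search for the AUC-maximizing weights.

    ``per_encoding_scores`` should be out-of-fold scores so the weights
    are not fit on resubstitution optimism. Ties break toward the
    lexicographically smallest weight vector in ``order`` (canonical
    encoding order by default).
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    if order is None:
        order = [e for e in ENCODINGS if e in per_encoding_scores]
        order += [e for e in per_encoding_scores if e not in order]
    if set(order) != set(per_encoding_scores):
        raise ValueError("order must cover exactly the score keys")
    S = np.stack([per_encoding_scores[e].scores for e in order], axis=1)  # (n, enc)
    best_auc, best = -np.inf, None
    for w in simplex_grid(len(order), step):
        auc = roc_auc_score(labels, S @ np.array(w))
        if auc > best_auc:  # strict: first (lex-smallest) max wins
            best_auc, best = auc, w
    return FusionWeights(dict(zip(order, best)), resolution=step)
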