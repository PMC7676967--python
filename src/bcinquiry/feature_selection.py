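"""Chi-squared question importance and top-k selection.

For each candidate combination the 60 questions are ranked by a
chi-squared statistic measuring how strongly the answers to a question
depend on the constitution label; the top-k questions form that
combination's personalized question set. Two formulations are provided:

``feature-sum`` (default)
    Answer values are treated as counts: the observed statistic for item j
    and class c is the sum of that item's answers over class-c rows, the
    expected value allocates the item's grand total by class frequency, and
    the score is the usual sum of (O-E)^2/E over classes. This is the
    classic text-classification chi-squared feature score (and what
    ``sklearn.feature_selection.chi2`` computes).

``contingency``
    Pearson's chi-squared on the 5 x C contingency table of answer-level
    counts per class. Cells with zero expected count contribute 0.

Both are filter methods: they look only at the data, never at a classifier.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from sklearn.feature_selection import chi2 as _sklearn_chi2

from .datasets import LabeledDataset

__all__ = ["FeatureRanking", "chi2_scores", "select_top_k"]

Chi2Method = Literal["feature-sum", "contingency"]
DEFAULT_METHOD: Chi2Method = "feature-sum"


@dataclasses.dataclass(frozen=True)
class FeatureRanking:
    """Importance score per item id, plus the variant that produced it."""

    item_ids: tuple[int, ...]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        if s.shape != (len(self.item_ids),):
            raise ValueError("one score per item id required")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("scores must be finite and non-negative")
        object.__setattr__(self, "scores", s)

    def score_of(self, item_id: int) -> float:
        return float(self.scores[self.item_ids.index(item_id)])

    def to_records(self) -> list[dict]:
        order = ranked_order(self)
        rank = {self.item_ids[j]: r + 1 for r, j in enumerate(order)}
        return [
            {"item_id": i, "score": float(s), "rank": rank[i]}
            for i, s in zip(self.item_ids, self.scores)
        ]


def _contingency_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    classes, y_idx = np.unique(y, return_inverse=True)
    n = X.shape[0]
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        levels, x_idx = np.unique(X[:, j], return_inverse=True)
        obs = np.zeros((len(levels), len(classes)))
        np.add.at(obs, (x_idx, y_idx), 1.0)
        exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / n
        with np.errstate(invalid="ignore", divide="ignore"):
            cell = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        scores[j] = cell.sum()
    return scores


def chi2_scores(
    dataset: LabeledDataset, method: Chi2Method = DEFAULT_METHOD
) -> FeatureRanking:
    """Score every question's importance for separating the dataset's labels."""
    if dataset.n_samples < 1:
        raise ValueError("need at least one row")
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("need >= 2 classes to score question importance")
    if method == "feature-sum":
        scores, _ = _sklearn_chi2(dataset.X, dataset.y)
        scores = np.nan_to_num(scores, nan=0.0)  # constant columns: O == E
    elif method == "contingency":
        scores = _contingency_scores(np.asarray(dataset.X), dataset.y)
    else:
        raise ValueError(f"unknown chi2 method {method!r}")
    return FeatureRanking(item_ids=dataset.item_ids, scores=scores, method=method)


def ranked_order(ranking: FeatureRanking) -> np.ndarray:
    """Indices into ``ranking.item_ids`` by descending score, then ascending id."""
    ids = np.asarray(ranking.item_ids)
    return np.lexsort((ids, -ranking.scores))


def select_top_k(ranking: FeatureRanking, k: int) -> list[int]:
    """The k item ids with the highest scores (ties to the lower item id)."""
    n = len(ranking.item_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = ranked_order(ranking)[:k]
    return [ranking.item_ids[j] for j in order]
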