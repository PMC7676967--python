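"""Subscale scoring and constitution judgment (the labeling oracle).

Each constitution's subscale is scored in two steps:

* raw score — the sum of its item answers, with reverse-scored items
  contributing ``6 - answer``;
* transformed score — the raw score rescaled to [0, 100]:
  ``(raw - n_items) / (4 * n_items) * 100``.

The judgment standard then assigns per-constitution statuses (yes /
tendency / no) from the thresholds, and a single primary label is taken as
the constitution with the maximal transformed score. Transformed scores are
rationals with denominator ``4 * n_items``, so argmax comparisons are exact
in double precision; ties are resolved deterministically by the
constitution listing order — by default the *last* listed type among the
tied maxima wins (the convention of a scanning-max that updates on ">=",
which reproduces the reference label distribution), configurable to the
first.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

from .constitutions import Constitution, CONSTITUTIONS, N_CONSTITUTIONS
from .datasets import LabeledDataset
from .questionnaire import QuestionnaireSpec, validate_responses

__all__ = [
    "Status",
    "JudgmentResult",
    "raw_subscale_score",
    "transformed_score",
    "transformed_scores",
    "judge",
    "label_dataset",
]

TieBreak = Literal["last", "first"]
DEFAULT_TIE_BREAK: TieBreak = "last"

Status = Literal["yes", "tendency", "no"]


@dataclasses.dataclass(frozen=True)
class JudgmentResult:
    """Per-constitution statuses plus the single primary label for one row."""

    statuses: dict[Constitution, Status]
    primary_label: Constitution
    scores: dict[Constitution, float]


def raw_subscale_score(
    spec: QuestionnaireSpec,
    answers: Sequence[int] | np.ndarray,
    constitution: Constitution,
) -> int:
    """Raw score of one respondent on one constitution's subscale.

    Normal items contribute their answer; reverse-scored items contribute
    ``6 - answer``. Range: ``[n_items, 5 * n_items]``.
    """
    if not isinstance(constitution, Constitution):
        constitution = Constitution.from_label(str(constitution))
    answers = np.asarray(answers)
    if answers.shape != (spec.n_items,):
        raise ValueError(
            f"expected {spec.n_items} answers, got shape {answers.shape}"
        )
    sub = spec.subscale(constitution)
    pos = {it.id: j for j, it in enumerate(spec.items)}
    rev = spec.reversed_items_of(constitution)
    total = 0
    for i in sub.item_ids:
        a = int(answers[pos[i]])
        total += (6 - a) if i in rev else a
    return total


def transformed_score(raw: int | np.ndarray, n_items: int) -> float | np.ndarray:
    """Rescale a raw subscale score to [0, 100]."""
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    raw_arr = np.asarray(raw)
    if np.any(raw_arr < n_items) or np.any(raw_arr > 5 * n_items):
        raise ValueError(
            f"raw score out of [{n_items}, {5 * n_items}] for n_items={n_items}"
        )
    out = (raw_arr - n_items) / (4.0 * n_items) * 100.0
    return float(out) if np.isscalar(raw) else out


def transformed_scores(
    spec: QuestionnaireSpec, responses: np.ndarray
) -> np.ndarray:
    """Vectorized ``(m, 9)`` transformed-score matrix, one column per type."""
    X = validate_responses(spec, responses)
    pos = {it.id: j for j, it in enumerate(spec.items)}
    out = np.empty((X.shape[0], N_CONSTITUTIONS), dtype=np.float64)
    for c in CONSTITUTIONS:
        sub = spec.subscale(c)
        rev = spec.reversed_items_of(c)
        cols = [pos[i] for i in sub.item_ids]
        vals = X[:, cols].astype(np.int64)
        flip = np.array([i in rev for i in sub.item_ids])
        if flip.any():
            vals = np.where(flip[None, :], 6 - vals, vals)
        raw = vals.sum(axis=1)
        n = sub.n_items
        out[:, c] = (raw - n) / (4.0 * n) * 100.0
    return out


def _argmax_labels(scores: np.ndarray, tie_break: TieBreak) -> np.ndarray:
    """Row-wise argmax over the 9 score columns with a fixed tie rule."""
    if tie_break == "first":
        return np.argmax(scores, axis=1)
    if tie_break == "last":
        flipped = scores[:, ::-1]
        return scores.shape[1] - 1 - np.argmax(flipped, axis=1)
    raise ValueError(f"tie_break must be 'first' or 'last', got {tie_break!r}")


def _statuses_row(
    spec: QuestionnaireSpec, scores: np.ndarray
) -> dict[Constitution, Status]:
    thr = spec.thresholds
    statuses: dict[Constitution, Status] = {}
    unbalanced = [c for c in CONSTITUTIONS if c is not Constitution.BALANCED]
    for c in unbalanced:
        s = scores[c]
        statuses[c] = (
            "yes" if s >= thr.yes_cutoff
            else "tendency" if s >= thr.tendency_cutoff
            else "no"
        )
    balanced_ok = scores[Constitution.BALANCED] >= thr.balanced_yes_cutoff and all(
        scores[c] < thr.balanced_other_max for c in unbalanced
    )
    statuses[Constitution.BALANCED] = "yes" if balanced_ok else "no"
    return statuses


def judge(
    spec: QuestionnaireSpec,
    scores: Sequence[float] | np.ndarray,
    tie_break: TieBreak = DEFAULT_TIE_BREAK,
) -> JudgmentResult:
    """Judge one respondent from their 9 transformed scores.

    Statuses follow the threshold standard; the primary label is the argmax
    of the transformed scores and is deliberately independent of the
    statuses, so that exactly one label is assigned per respondent.
    """
    arr = np.asarray(scores, dtype=np.float64)
    if arr.shape != (N_CONSTITUTIONS,):
        raise ValueError(f"need {N_CONSTITUTIONS} scores, got shape {arr.shape}")
    label = Constitution(int(_argmax_labels(arr[None, :], tie_break)[0]))
    return JudgmentResult(
        statuses=_statuses_row(spec, arr),
        primary_label=label,
        scores={c: float(arr[c]) for c in CONSTITUTIONS},
    )


def label_dataset(
    spec: QuestionnaireSpec,
    responses: np.ndarray,
    tie_break: TieBreak = DEFAULT_TIE_BREAK,
) -> LabeledDataset:
    """Label every row of a response matrix with its primary constitution."""
    X = validate_responses(spec, responses)
    if X.shape[0] == 0:
        return LabeledDataset(
            X=X.reshape(0, spec.n_items),
            y=np.empty(0, dtype=np.int64),
            item_ids=tuple(it.id for it in spec.items),
        )
    scores = transformed_scores(spec, X)
    y = _argmax_labels(scores, tie_break)
    return LabeledDataset(X=X, y=y, item_ids=tuple(it.id for it in spec.items))
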