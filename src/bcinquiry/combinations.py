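"""Three-constitution candidate combinations.

An upstream image-based classifier narrows a patient's constitution to its
three most probable types. To cover every possible such output, all
C(9,3) = 84 unordered triples of distinct constitution types are
enumerated, and each gets its own training subset: the rows of the original
dataset whose label falls inside the triple.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Sequence

import numpy as np

from .constitutions import Constitution, CONSTITUTIONS
from .datasets import LabeledDataset

__all__ = [
    "Combination",
    "enumerate_combinations",
    "combination_for",
    "filter_dataset",
    "project_questions",
]

logger = logging.getLogger(__name__)

N_COMBINATIONS = 84  # C(9, 3)


@dataclasses.dataclass(frozen=True)
class Combination:
    """An unordered triple of distinct constitution types.

    ``index`` runs 1..84 in lexicographic order of the member ordinals and
    is stable across runs; equality ignores it and compares members only.
    """

    members: frozenset[Constitution]
    index: int

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ValueError(f"a combination has exactly 3 members, got {len(self.members)}")
        object.__setattr__(self, "members", frozenset(Constitution(c) for c in self.members))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Combination):
            return NotImplemented
        return self.members == other.members

    def __hash__(self) -> int:
        return hash(self.members)

    @property
    def ordered(self) -> tuple[Constitution, Constitution, Constitution]:
        return tuple(sorted(self.members))

    @property
    def names(self) -> tuple[str, str, str]:
        return tuple(c.label for c in self.ordered)

    def __str__(self) -> str:
        return f"C{self.index}({'; '.join(self.names)})"


def enumerate_combinations() -> list[Combination]:
    """All 84 three-type combinations, indexed 1..84 lexicographically."""
    return [
        Combination(members=frozenset(trip), index=i)
        for i, trip in enumerate(itertools.combinations(CONSTITUTIONS, 3), start=1)
    ]


def combination_for(members: Iterable[Constitution | str]) -> Combination:
    """Resolve the registered combination containing exactly these members."""
    resolved = frozenset(
        c if isinstance(c, Constitution) else Constitution.from_label(str(c))
        for c in members
    )
    for comb in enumerate_combinations():
        if comb.members == resolved:
            return comb
    raise ValueError(f"not a valid 3-type combination: {sorted(resolved)}")


def filter_dataset(dataset: LabeledDataset, combination: Combination) -> LabeledDataset:
    """Rows of ``dataset`` whose label is one of the combination's members.

    Row order is preserved. An empty result is allowed but logged as a
    warning, since a model cannot be trained from it.
    """
    wanted = np.isin(dataset.y, [int(c) for c in combination.members])
    if not wanted.any():
        logger.warning("combination %s matched no rows", combination)
    return LabeledDataset(
        X=dataset.X[wanted], y=dataset.y[wanted], item_ids=dataset.item_ids
    )


def project_questions(
    dataset: LabeledDataset, question_set: Sequence[int]
) -> LabeledDataset:
    """Restrict the answer matrix to ``question_set`` columns, in that order."""
    qs = list(question_set)
    if len(set(qs)) != len(qs):
        raise ValueError(f"duplicate item ids in question set: {qs}")
    col = {i: j for j, i in enumerate(dataset.item_ids)}
    missing = [i for i in qs if i not in col]
    if missing:
        raise ValueError(f"unknown item ids {missing}; dataset has {dataset.item_ids}")
    cols = [col[i] for i in qs]
    return LabeledDataset(X=dataset.X[:, cols], y=dataset.y, item_ids=tuple(qs))
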