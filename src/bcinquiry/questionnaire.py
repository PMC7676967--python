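"""Questionnaire structure: items, subscales, judgment thresholds.

The instrument modelled here is the 60-item Constitution in Chinese Medicine
Questionnaire (CCMQ): five-point Likert items (1 = never … 5 = always), nine
subscales (one per constitution type), some items reverse-scored, and a
published judgment standard that converts subscale scores into yes /
tendency / no statuses per constitution.

The item-to-subscale assignment ships as editable package data
(``data/ccmq_default.yaml``) rather than being hard-coded: the mapping is
instrument metadata, and deployments holding the licensed instrument text
should verify or replace the default against the published standard.
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

_logger = logging.getLogger(__name__)

from .constitutions import Constitution, N_CONSTITUTIONS

N_ITEMS = 60
ANSWER_MIN = 1
ANSWER_MAX = 5

__all__ = [
    "Item",
    "Subscale",
    "JudgmentThresholds",
    "QuestionnaireSpec",
    "QuestionnaireError",
    "load_questionnaire",
    "default_questionnaire",
    "validate_responses",
    "N_ITEMS",
    "ANSWER_MIN",
    "ANSWER_MAX",
]


class QuestionnaireError(ValueError):
    """Structured questionnaire validation failure.

    ``field`` names the offending part of the configuration so callers can
    report actionable errors.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


@dataclasses.dataclass(frozen=True)
class Item:
    """A single questionnaire item.

    Item 60 merges the two gender-conditional questions of the printed
    instrument (60_1/60_2) into one gender-neutral item, so ids run 1..60.
    """

    id: int
    text: str = ""
    reverse_scored: bool = False


@dataclasses.dataclass(frozen=True)
class Subscale:
    """The item set scored for one constitution.

    ``reversed_items`` lists items reverse-scored *within this subscale*;
    this is in addition to any item-level ``reverse_scored`` flag. The
    distinction matters when an item is shared between subscales and keyed
    oppositely in each (the balanced scale of the CCMQ reuses symptom items
    of unbalanced scales with reversed keying).
    """

    constitution: Constitution
    item_ids: tuple[int, ...]
    reversed_items: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        extra = set(self.reversed_items) - set(self.item_ids)
        if extra:
            raise QuestionnaireError(
                "subscales",
                f"{self.constitution.label}: reversed items {sorted(extra)} "
                "not in the subscale",
            )

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclasses.dataclass(frozen=True)
class JudgmentThresholds:
    """Cut-offs of the judgment standard, in transformed-score units (0-100).

    An unbalanced constitution is "yes" at or above ``yes_cutoff`` and a
    "tendency" at or above ``tendency_cutoff``; the balanced type requires
    its own score at or above ``balanced_yes_cutoff`` while every unbalanced
    score stays below ``balanced_other_max``.
    """

    yes_cutoff: float = 40.0
    tendency_cutoff: float = 30.0
    balanced_yes_cutoff: float = 60.0
    balanced_other_max: float = 30.0

    def validate(self) -> None:
        if not (0 <= self.tendency_cutoff <= self.yes_cutoff <= 100):
            raise QuestionnaireError(
                "thresholds",
                "require 0 <= tendency_cutoff <= yes_cutoff <= 100, got "
                f"tendency={self.tendency_cutoff}, yes={self.yes_cutoff}",
            )
        if not (0 <= self.balanced_other_max <= self.balanced_yes_cutoff <= 100):
            raise QuestionnaireError(
                "thresholds",
                "require 0 <= balanced_other_max <= balanced_yes_cutoff <= 100",
            )


@dataclasses.dataclass(frozen=True)
class QuestionnaireSpec:
    """A validated questionnaire: items, subscales and judgment thresholds.

    By default each item may be scored by at most one subscale; set
    ``allow_shared_items`` (config key of the same name) for instruments
    whose balanced scale reuses items of other scales.
    """

    items: tuple[Item, ...]
    subscales: tuple[Subscale, ...]
    thresholds: JudgmentThresholds = JudgmentThresholds()
    answer_min: int = ANSWER_MIN
    answer_max: int = ANSWER_MAX
    allow_shared_items: bool = False

    def __post_init__(self) -> None:
        self._validate()

    @property
    def n_items(self) -> int:
        return len(self.items)

    def item(self, item_id: int) -> Item:
        return self._items_by_id()[item_id]

    def _items_by_id(self) -> dict[int, Item]:
        return {it.id: it for it in self.items}

    def subscale(self, constitution: Constitution) -> Subscale:
        for s in self.subscales:
            if s.constitution == constitution:
                return s
        raise QuestionnaireError("subscales", f"no subscale for {constitution!r}")

    @property
    def reverse_scored_ids(self) -> frozenset[int]:
        return frozenset(it.id for it in self.items if it.reverse_scored)

    def reversed_items_of(self, constitution: Constitution) -> frozenset[int]:
        """Items effectively reverse-scored within a constitution's subscale."""
        sub = self.subscale(constitution)
        item_level = self.reverse_scored_ids & set(sub.item_ids)
        return frozenset(item_level | set(sub.reversed_items))

    def _validate(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise QuestionnaireError("items", f"duplicate item id(s) {dup}")
        known = set(ids)
        for it in self.items:
            if it.id < 1:
                raise QuestionnaireError("items", f"item id {it.id} < 1")
        constitutions = [s.constitution for s in self.subscales]
        if len(set(constitutions)) != N_CONSTITUTIONS or len(constitutions) != N_CONSTITUTIONS:
            missing = sorted(
                c.label for c in Constitution if c not in set(constitutions)
            )
            raise QuestionnaireError(
                "subscales",
                f"need exactly one subscale per constitution; missing {missing}"
                if missing
                else "duplicate constitution subscales",
            )
        seen: dict[int, Constitution] = {}
        for s in self.subscales:
            if not s.item_ids:
                raise QuestionnaireError(
                    "subscales", f"{s.constitution.label} subscale is empty"
                )
            if len(set(s.item_ids)) != len(s.item_ids):
                raise QuestionnaireError(
                    "subscales", f"{s.constitution.label} lists an item twice"
                )
            for i in s.item_ids:
                if i not in known:
                    raise QuestionnaireError(
                        "subscales",
                        f"{s.constitution.label} references unknown item {i}",
                    )
                if i in seen:
                    if not self.allow_shared_items:
                        raise QuestionnaireError(
                            "subscales",
                            f"item {i} assigned to both {seen[i].label} and "
                            f"{s.constitution.label} (set allow_shared_items "
                            "for instruments that share items)",
                        )
                    _logger.info(
                        "item %d shared by %s and %s subscales",
                        i, seen[i].label, s.constitution.label,
                    )
                else:
                    seen[i] = s.constitution
        self.thresholds.validate()

    def _require_full_length(self) -> None:
        if self.n_items != N_ITEMS:
            raise QuestionnaireError(
                "items", f"item count {self.n_items} != {N_ITEMS}"
            )

    # ---------------------------------------------------------------- I/O

    def to_dict(self) -> dict:
        return {
            "items": [
                {"id": it.id, "text": it.text, "reverse_scored": it.reverse_scored}
                for it in self.items
            ],
            "subscales": {
                s.constitution.label: (
                    {"items": list(s.item_ids), "reversed": list(s.reversed_items)}
                    if s.reversed_items
                    else list(s.item_ids)
                )
                for s in self.subscales
            },
            "thresholds": dataclasses.asdict(self.thresholds),
            "allow_shared_items": self.allow_shared_items,
        }

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "QuestionnaireSpec":
        try:
            raw_items = cfg["items"]
            raw_subscales = cfg["subscales"]
        except (KeyError, TypeError) as exc:
            raise QuestionnaireError("config", f"missing top-level key: {exc}")
        items = tuple(
            Item(
                id=int(d["id"]),
                text=str(d.get("text", "")),
                reverse_scored=bool(d.get("reverse_scored", False)),
            )
            for d in raw_items
        )
        subscales = []
        for name, val in raw_subscales.items():
            if isinstance(val, Mapping):
                ids = tuple(int(i) for i in val["items"])
                rev = tuple(int(i) for i in val.get("reversed", ()))
            else:
                ids, rev = tuple(int(i) for i in val), ()
            subscales.append(
                Subscale(Constitution.from_label(name), ids, reversed_items=rev)
            )
        thr = JudgmentThresholds(**cfg.get("thresholds", {}))
        return cls(
            items=items,
            subscales=tuple(subscales),
            thresholds=thr,
            allow_shared_items=bool(cfg.get("allow_shared_items", False)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_yaml(text: str) -> QuestionnaireSpec:
    return QuestionnaireSpec.from_dict(yaml.safe_load(text))


def default_questionnaire() -> QuestionnaireSpec:
    """The package-shipped 60-item CCMQ configuration.

    The subscale sizes and judgment thresholds follow the published
    standard; the concrete item-id blocks are a reconstruction and should be
    verified against the printed instrument before clinical use.
    """
    text = resources.files("bcinquiry.data").joinpath("ccmq_default.yaml").read_text()
    spec = _load_yaml(text)
    spec._require_full_length()
    return spec


def load_questionnaire(path: str | Path | None = None) -> QuestionnaireSpec:
    """Load a questionnaire configuration, or the shipped default.

    Parameters
    ----------
    path
        YAML (or JSON, a YAML subset) file with keys ``items``,
        ``subscales`` and optionally ``thresholds``. When omitted the
        shipped 60-item default is returned.
    """
    if path is None:
        return default_questionnaire()
    spec = _load_yaml(Path(path).read_text())
    return spec


def validate_responses(
    spec: QuestionnaireSpec, responses: np.ndarray | Sequence[Sequence[int]]
) -> np.ndarray:
    """Check a response matrix against the questionnaire.

    Returns the responses as an ``(m, n_items)`` integer array. Raises
    ``ValueError`` naming the first offending row/item on out-of-range
    entries, and on a column count that does not match the questionnaire.
    """
    arr = np.asarray(responses)
    if arr.ndim != 2:
        raise ValueError(f"responses must be 2-D, got shape {arr.shape}")
    if arr.shape[1] != spec.n_items:
        raise ValueError(
            f"responses have {arr.shape[1]} columns, questionnaire has "
            f"{spec.n_items} items"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("responses must be integers")
        arr = arr.astype(np.int64)
    bad = (arr < spec.answer_min) | (arr > spec.answer_max)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"answer out of range [{spec.answer_min}, {spec.answer_max}]: "
            f"row {r}, item {spec.items[c].id}, value {arr[r, c]}"
        )
    return arr
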