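"""The nine TCM body-constitution types.

Body constitution (BC) theory in Traditional Chinese Medicine classifies a
person's stable health state into one balanced and eight unbalanced types.
The enum order below is the canonical listing order; it doubles as the
deterministic tie-break order everywhere a single winner must be chosen.
"""

from __future__ import annotations

import enum


class Constitution(enum.IntEnum):
    """One of the nine body-constitution types, ordinal-valued 0..8."""

    BALANCED = 0
    QI_DEFICIENT = 1
    YANG_DEFICIENT = 2
    YIN_DEFICIENT = 3
    PHLEGM_DAMPNESS = 4
    DAMP_HEAT = 5
    STAGNANT_BLOOD = 6
    STAGNANT_QI = 7
    INHERITED_SPECIAL = 8

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Constitution":
        """Resolve a constitution from its display name, enum name, or alias."""
        key = label.strip().lower().replace("-", " ").replace("_", " ")
        try:
            return _ALIASES[key]
        except KeyError:
            raise ValueError(
                f"unknown constitution {label!r}; expected one of "
                f"{[c.label for c in cls]}"
            ) from None


_LABELS = {
    Constitution.BALANCED: "Balanced",
    Constitution.QI_DEFICIENT: "Qi-deficient",
    Constitution.YANG_DEFICIENT: "Yang-deficient",
    Constitution.YIN_DEFICIENT: "Yin-deficient",
    Constitution.PHLEGM_DAMPNESS: "Phlegm-dampness",
    Constitution.DAMP_HEAT: "Damp-heat",
    Constitution.STAGNANT_BLOOD: "Stagnant Blood",
    Constitution.STAGNANT_QI: "Stagnant Qi",
    Constitution.INHERITED_SPECIAL: "Inherited Special",
}

_ALIASES: dict[str, Constitution] = {}
for _c, _lbl in _LABELS.items():
    _ALIASES[_lbl.lower().replace("-", " ")] = _c
    _ALIASES[_c.name.lower().replace("_", " ")] = _c
# common one-word shorthands
_ALIASES.update(
    {
        "gentleness": Constitution.BALANCED,
        "blood stasis": Constitution.STAGNANT_BLOOD,
        "qi stagnation": Constitution.STAGNANT_QI,
        "special diathesis": Constitution.INHERITED_SPECIAL,
    }
)

CONSTITUTIONS: tuple[Constitution, ...] = tuple(Constitution)
N_CONSTITUTIONS = len(CONSTITUTIONS)
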