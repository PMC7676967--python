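"""Labeled response datasets and their delimited-text interchange format.

A dataset couples an ``(m, n)`` integer answer matrix (rows = respondents,
columns = questionnaire items) with one constitution label per row. On disk
it is a CSV/TSV table with columns ``q<item id>...`` plus a ``label`` column
holding constitution names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import numpy as np
import pandas as pd

from .constitutions import Constitution

__all__ = ["LabeledDataset"]


@dataclasses.dataclass(frozen=True)
class LabeledDataset:
    """An answer matrix with one constitution label per row.

    ``item_ids[j]`` is the questionnaire item id of column ``j``; labels are
    stored as constitution ordinals (``Constitution`` values).
    """

    X: np.ndarray
    y: np.ndarray
    item_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X)
        y = np.asarray(self.y, dtype=np.int64)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError(
                f"label count {y.shape} does not match row count {X.shape[0]}"
            )
        if X.shape[1] != len(self.item_ids):
            raise ValueError("item_ids length must match column count")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "item_ids", tuple(int(i) for i in self.item_ids))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def labels(self) -> list[Constitution]:
        return [Constitution(v) for v in self.y]

    def label_counts(self) -> dict[Constitution, int]:
        """Per-constitution row counts (zero for absent labels)."""
        counts = np.bincount(self.y, minlength=len(Constitution))
        return {c: int(counts[c]) for c in Constitution}

    def classes(self) -> tuple[Constitution, ...]:
        return tuple(Constitution(v) for v in np.unique(self.y))

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"q{i}" for i in self.item_ids])
        df["label"] = [Constitution(v).label for v in self.y]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        if "label" not in df.columns:
            raise ValueError("dataset table needs a 'label' column")
        qcols = [c for c in df.columns if c.startswith("q")]
        item_ids = tuple(int(c[1:]) for c in qcols)
        X = df[qcols].to_numpy(dtype=np.int64)
        y = np.array([Constitution.from_label(v) for v in df["label"]], dtype=np.int64)
        return cls(X=X, y=y, item_ids=item_ids)

    def save(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def load(cls, path: str | Path, sep: str | None = None) -> "LabeledDataset":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))
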