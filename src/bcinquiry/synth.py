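"""Synthetic respondent generation.

Training data is simulated: each virtual respondent answers every item with
an independent uniform draw from {1..5}, and the scoring standard labels the
resulting answer vector. This produces arbitrarily large labeled datasets
whose label distribution is governed entirely by the subscale structure
(smaller subscales have higher score variance and win the argmax more
often). Uniform answers carry none of the item correlations of real
respondents; see the methods note for what that does and does not validate.
"""

from __future__ import annotations

import zlib

import numpy as np

from .datasets import LabeledDataset
from .questionnaire import QuestionnaireSpec, default_questionnaire
from .scoring import DEFAULT_TIE_BREAK, TieBreak, label_dataset

__all__ = ["generate_responses", "build_original_dataset", "child_seed"]


def child_seed(seed: int, stream: str) -> int:
    """Derive a deterministic child seed (< 2**31) for a named substream."""
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_responses(
    m: int, seed: int, n_items: int = 60
) -> np.ndarray:
    """Generate ``m`` uniform-random answer rows on ``n_items`` items.

    Entries are i.i.d. uniform on {1..5}; the same ``(m, seed)`` pair always
    yields the identical matrix.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    rng = np.random.default_rng(seed)
    return rng.integers(1, 6, size=(m, n_items), dtype=np.int8)


def build_original_dataset(
    spec: QuestionnaireSpec | None = None,
    m: int = 1_000_000,
    seed: int = 0,
    tie_break: TieBreak = DEFAULT_TIE_BREAK,
) -> LabeledDataset:
    """Generate and label the original dataset of ``m`` simulated respondents."""
    if spec is None:
        spec = default_questionnaire()
    X = generate_responses(m, seed, n_items=spec.n_items)
    return label_dataset(spec, X, tie_break=tie_break)
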