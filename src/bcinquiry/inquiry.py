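"""Adaptive inquiry sessions.

The front-end of the system: an upstream (image-based) classifier supplies
the patient's three most probable constitution types — either directly or
as a 9-way probability vector — and the session serves exactly that
combination's personalized questions, then predicts one constitution from
the answers. The prediction is closed-world: it is always one of the three
candidates.
"""

from __future__ import annotations

import dataclasses
import time
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bcim import CombinationModel, ModelRegistry
from .constitutions import Constitution, CONSTITUTIONS
from .questionnaire import ANSWER_MAX, ANSWER_MIN

__all__ = [
    "CandidateTriple",
    "InquirySession",
    "top3_from_probabilities",
    "start_session",
    "submit_answers",
    "session_report",
]


@dataclasses.dataclass(frozen=True)
class CandidateTriple:
    """Three candidate constitution types, optionally with source probabilities."""

    members: frozenset[Constitution]
    probabilities: dict[Constitution, float] | None = None

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ValueError(f"a candidate triple has 3 members, got {len(self.members)}")

    @property
    def ordered(self) -> tuple[Constitution, ...]:
        if self.probabilities:
            return tuple(
                sorted(self.members, key=lambda c: (-self.probabilities.get(c, 0.0), c))
            )
        return tuple(sorted(self.members))

    @classmethod
    def of(cls, members: Iterable[Constitution | str]) -> "CandidateTriple":
        return cls(
            members=frozenset(
                c if isinstance(c, Constitution) else Constitution.from_label(str(c))
                for c in members
            )
        )


def top3_from_probabilities(probs: Sequence[float] | np.ndarray) -> CandidateTriple:
    """The three most probable constitutions from a 9-way probability vector.

    Ties at the rank-3 boundary go to the lower ordinal, so the result is
    deterministic for any input.
    """
    arr = np.asarray(probs, dtype=np.float64)
    if arr.shape != (len(CONSTITUTIONS),):
        raise ValueError(f"need {len(CONSTITUTIONS)} probabilities, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("probabilities must be finite and non-negative")
    order = np.lexsort((np.arange(len(arr)), -arr))[:3]
    members = frozenset(Constitution(int(i)) for i in order)
    return CandidateTriple(
        members=members,
        probabilities={Constitution(int(i)): float(arr[i]) for i in order},
    )


@dataclasses.dataclass
class InquirySession:
    """One patient's pass through the personalized questionnaire."""

    triple: CandidateTriple
    model: CombinationModel
    questions: list[int]
    collected_answers: dict[int, int] = dataclasses.field(default_factory=dict)
    prediction: Constitution | None = None
    started_at: float = dataclasses.field(default_factory=time.perf_counter)
    elapsed_s: float | None = None


def start_session(registry: ModelRegistry, triple: CandidateTriple) -> InquirySession:
    """Open a session serving the triple's personalized question list."""
    model = registry.get(triple.members)
    return InquirySession(
        triple=triple, model=model, questions=list(model.question_set)
    )


def submit_answers(
    session: InquirySession, answers: Mapping[int, int]
) -> InquirySession:
    """Record the patient's answers and predict their constitution.

    ``answers`` must cover exactly the session's questions with values in
    the Likert range; the prediction is the model's label for the answer
    vector and always lies within the candidate triple.
    """
    asked = set(session.questions)
    got = set(answers)
    problems = []
    if asked - got:
        problems.append(f"missing answers for items {sorted(asked - got)}")
    if got - asked:
        problems.append(f"unexpected answers for items {sorted(got - asked)}")
    bad = sorted(
        i for i in (got & asked) if not ANSWER_MIN <= int(answers[i]) <= ANSWER_MAX
    )
    if bad:
        problems.append(
            f"answers out of [{ANSWER_MIN}, {ANSWER_MAX}] for items {bad}"
        )
    if problems:
        raise ValueError("; ".join(problems))
    vec = np.array([[int(answers[i]) for i in session.questions]], dtype=np.float64)
    pred = Constitution(int(session.model.predict(vec)[0]))
    session.collected_answers = {i: int(answers[i]) for i in session.questions}
    session.prediction = pred
    session.elapsed_s = time.perf_counter() - session.started_at
    return session


def session_report(session: InquirySession) -> dict:
    """A structured summary: candidates, questions, answers, prediction, time."""
    if session.prediction is None:
        raise ValueError("session has no prediction yet; submit answers first")
    return {
        "candidates": [c.label for c in session.triple.ordered],
        "questions": list(session.questions),
        "n_questions": len(session.questions),
        "answers": dict(session.collected_answers),
        "prediction": session.prediction.label,
        "elapsed_s": session.elapsed_s,
    }


def percent_reduction(baseline: float, reduced: float) -> float:
    """Percentage reduction of ``reduced`` relative to ``baseline``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return (baseline - reduced) / baseline * 100.0
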