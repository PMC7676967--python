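import numpy as np
import pytest

from bcinquiry.bcim import train_all
from bcinquiry.combinations import filter_dataset, project_questions
from bcinquiry.constitutions import Constitution
from bcinquiry.inquiry import (
    CandidateTriple,
    percent_reduction,
    session_report,
    start_session,
    submit_answers,
    top3_from_probabilities,
)
from bcinquiry.questionnaire import Item, QuestionnaireSpec, Subscale
from bcinquiry.synth import build_original_dataset


@pytest.fixture(scope="module")
def toy_registry():
    items = tuple(Item(id=i) for i in range(1, 10))
    subscales = tuple(Subscale(c, (int(c) + 1,)) for c in Constitution)
    spec = QuestionnaireSpec(items=items, subscales=subscales)
    ds = build_original_dataset(spec, m=6000, seed=8)
    return spec, ds, train_all(ds, classifier_kind="lda", k_policy=3, seed=3)


class TestTop3:
    def test_peaked_vector(self):
        probs = np.zeros(9)
        probs[Constitution.YIN_DEFICIENT] = 0.6
        probs[Constitution.QI_DEFICIENT] = 0.25
        probs[Constitution.BALANCED] = 0.1
        triple = top3_from_probabilities(probs)
        assert triple.members == {
            Constitution.YIN_DEFICIENT,
            Constitution.QI_DEFICIENT,
            Constitution.BALANCED,
        }
        assert triple.ordered[0] is Constitution.YIN_DEFICIENT

    def test_uniform_vector_gives_lowest_ordinals(self):
        triple = top3_from_probabilities(np.full(9, 1 / 9))
        assert triple.members == set(list(Constitution)[:3])

    def test_tie_at_rank_boundary_goes_to_lower_ordinal(self):
        probs = np.array([0.3, 0.3, 0.1, 0.1, 0.1, 0.1, 0.0, 0.0, 0.0])
        triple = top3_from_probabilities(probs)
        # ranks 3..6 tied at 0.1: Yang-deficient (lowest ordinal) wins
        assert Constitution.YANG_DEFICIENT in triple.members
        assert Constitution.YIN_DEFICIENT not in triple.members

    def test_negative_probability_rejected(self):
        probs = np.full(9, 0.2)
        probs[4] = -0.1
        with pytest.raises(ValueError):
            top3_from_probabilities(probs)


class TestSession:
    def test_questions_come_from_model(self, toy_registry):
        _, _, registry = toy_registry
        triple = CandidateTriple.of(["Yin-deficient", "Qi-deficient", "Balanced"])
        session = start_session(registry, triple)
        model = registry.get(triple.members)
        assert session.questions == list(model.question_set)
        assert len(set(session.questions)) == len(session.questions)
        assert set(session.questions) <= set(range(1, 61))

    def test_sessions_deterministic(self, toy_registry):
        _, _, registry = toy_registry
        triple = CandidateTriple.of(["Damp-heat", "Stagnant Qi", "Balanced"])
        s1 = start_session(registry, triple)
        s2 = start_session(registry, triple)
        assert s1.questions == s2.questions

    def test_prediction_always_in_triple(self, toy_registry, rng):
        _, _, registry = toy_registry
        triple = CandidateTriple.of(["Balanced", "Damp-heat", "Inherited Special"])
        for _ in range(10):
            session = start_session(registry, triple)
            answers = {q: int(a) for q, a in zip(session.questions, rng.integers(1, 6, len(session.questions)))}
            submit_answers(session, answers)
            assert session.prediction in triple.members

    def test_separable_answers_predict_target(self, toy_registry):
        _, _, registry = toy_registry
        triple = CandidateTriple.of(["Balanced", "Qi-deficient", "Yang-deficient"])
        session = start_session(registry, triple)
        # max out Qi-deficient's item (2), minimize the others
        answers = {q: (5 if q == 2 else 1) for q in session.questions}
        submit_answers(session, answers)
        assert session.prediction is Constitution.QI_DEFICIENT

    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda a: {k: v for k, v in list(a.items())[1:]}, "missing"),
            (lambda a: {**a, 60: 3}, "unexpected"),
            (lambda a: {**a, list(a)[0]: 9}, "out of"),
        ],
    )
    def test_bad_answers_rejected(self, toy_registry, mutate, message):
        _, _, registry = toy_registry
        triple = CandidateTriple.of(["Balanced", "Qi-deficient", "Yang-deficient"])
        session = start_session(registry, triple)
        answers = {q: 3 for q in session.questions}
        with pytest.raises(ValueError, match=message):
            submit_answers(session, mutate(answers))

    def test_report_fields(self, toy_registry):
        _, _, registry = toy_registry
        triple = CandidateTriple.of(["Balanced", "Qi-deficient", "Yang-deficient"])
        session = start_session(registry, triple)
        with pytest.raises(ValueError):
            session_report(session)  # no prediction yet
        submit_answers(session, {q: 2 for q in session.questions})
        report = session_report(session)
        assert report["n_questions"] == len(session.questions)
        assert report["prediction"] in report["candidates"] or report[
            "prediction"
        ] in [c.label for c in triple.members]
        assert report["elapsed_s"] >= 0

    def test_replay_matches_cv_accuracy(self, toy_registry):
        # replaying held-out respondents through a session reproduces the
        # model's cross-validated accuracy
        spec, _, registry = toy_registry
        probe = build_original_dataset(spec, m=4000, seed=123)
        model = registry.models[1]
        sub = filter_dataset(probe, model.combination)
        proj = project_questions(sub, model.question_set)
        agree = 0
        for r in range(200):
            session = start_session(registry, CandidateTriple(model.combination.members))
            answers = dict(zip(model.question_set, (int(v) for v in proj.X[r])))
            submit_answers(session, answers)
            agree += session.prediction == Constitution(int(proj.y[r]))
        assert agree / 200 >= model.metrics.accuracy_mean - 0.05


class TestReduction:
    def test_published_reduction_arithmetic(self):
        assert percent_reduction(60, 19) == pytest.approx(68.3, abs=0.05)
        assert percent_reduction(507, 100) == pytest.approx(80.3, abs=0.05)
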