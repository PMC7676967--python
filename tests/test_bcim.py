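import numpy as np
import pytest

from bcinquiry.bcim import (
    ConstitutionTripleClassifier,
    ModelRegistry,
    cross_validate,
    sweep_k,
    train_all,
    train_model,
)
from bcinquiry.combinations import combination_for, filter_dataset, project_questions
from bcinquiry.constitutions import Constitution
from bcinquiry.datasets import LabeledDataset
from bcinquiry.feature_selection import chi2_scores, select_top_k
from bcinquiry.synth import build_original_dataset


@pytest.fixture(scope="module")
def separable_triple(toy_spec_module):
    """Margin-separated toy triple: each row maxes exactly one subscale item.

    Rows of class c answer item c+1 with 4-5 and every other item with 1-2,
    so the argmax label is unambiguous and the classes are linearly
    separable with a margin.
    """
    from bcinquiry.scoring import label_dataset

    rng = np.random.default_rng(77)
    rows = []
    for c in range(3):
        X = rng.integers(1, 3, size=(600, 9))
        X[:, c] = rng.integers(4, 6, size=600)
        rows.append(X)
    X = np.vstack(rows)
    ds = label_dataset(toy_spec_module, X)
    comb = combination_for(["Balanced", "Qi-deficient", "Yang-deficient"])
    out = filter_dataset(ds, comb)
    assert out.n_samples == 1800  # argmax is unique by construction
    return out, comb


@pytest.fixture(scope="module")
def toy_spec_module():
    from bcinquiry.questionnaire import Item, QuestionnaireSpec, Subscale

    items = tuple(Item(id=i) for i in range(1, 10))
    subscales = tuple(
        Subscale(constitution=c, item_ids=(int(c) + 1,)) for c in Constitution
    )
    return QuestionnaireSpec(items=items, subscales=subscales)


class TestTrainModel:
    def test_trains_and_predicts_within_triple(self, separable_triple):
        sub, comb = separable_triple
        qs = select_top_k(chi2_scores(sub), 3)
        model = train_model(sub, qs, "lda", seed=1)
        pred = model.predict(project_questions(sub, qs).X.astype(float))
        assert set(np.unique(pred)) <= {int(c) for c in comb.members}

    def test_lda_deterministic_across_seeds(self, separable_triple):
        sub, _ = separable_triple
        qs = select_top_k(chi2_scores(sub), 3)
        Xq = project_questions(sub, qs).X.astype(float)
        m1 = train_model(sub, qs, "lda", seed=1)
        m2 = train_model(sub, qs, "lda", seed=2)
        assert np.array_equal(m1.predict(Xq), m2.predict(Xq))

    def test_missing_class_errors(self, separable_triple):
        sub, comb = separable_triple
        only = sub.y == int(Constitution.BALANCED)
        broken = LabeledDataset(sub.X[only], sub.y[only], sub.item_ids)
        with pytest.raises(ValueError):
            train_model(broken, [1, 2, 3], "lda", seed=0, combination=comb)


class TestCrossValidate:
    def test_separable_toy_panel_all_ones(self, separable_triple):
        # the toy triple's three one-item subscales fully determine the label
        sub, _ = separable_triple
        panel = cross_validate(sub, [1, 2, 3], "lda", seed=0)
        assert panel.accuracy_mean == pytest.approx(1.0)
        assert panel.macro_f == pytest.approx(1.0)

    def test_micro_identity_equals_pooled_accuracy(self, separable_triple):
        sub, _ = separable_triple
        panel = cross_validate(sub, [1, 2], "knn", seed=0)
        assert panel.micro_precision == panel.micro_recall == panel.micro_f
        # pooled accuracy equals the fold-size-weighted mean accuracy; with
        # near-equal folds it matches accuracy_mean to rounding
        assert panel.micro_f == pytest.approx(panel.accuracy_mean, abs=1e-3)

    def test_random_labels_near_chance(self, rng):
        X = rng.integers(1, 6, size=(2000, 5))
        y = rng.integers(0, 2, size=2000)
        ds = LabeledDataset(X, y, tuple(range(1, 6)))
        panel = cross_validate(ds, [1, 2, 3], "lda", seed=0)
        assert panel.accuracy_mean == pytest.approx(0.5, abs=0.05)

    def test_class_smaller_than_folds_errors(self):
        X = np.ones((7, 3), dtype=int)
        y = np.array([0, 0, 0, 0, 0, 1, 1])
        ds = LabeledDataset(X, y, (1, 2, 3))
        with pytest.raises(ValueError, match="fewer than"):
            cross_validate(ds, [1], "lda", seed=0)

    def test_folds_disjoint_and_cover(self, separable_triple):
        sub, _ = separable_triple
        panel = cross_validate(sub, [1, 2, 3], "lda", seed=0)
        assert panel.folds == 5
        assert len(panel.fold_accuracies) == 5
        assert panel.accuracy_best >= panel.accuracy_mean


class TestSweepK:
    def test_more_features_not_worse_on_separable(self, separable_triple):
        sub, _ = separable_triple
        res = sweep_k(sub, "lda", k_range=[1, 9], seed=0)
        assert res.accuracies[-1] >= res.accuracies[0]

    def test_smallest_good_k_at_most_best_k(self, separable_triple):
        sub, _ = separable_triple
        res = sweep_k(sub, "lda", k_range=[1, 2, 3, 5, 9], seed=0)
        assert res.smallest_good_k <= res.best_k
        # accuracy at the smallest good k is within tolerance of the max
        at_k = res.accuracies[res.ks.index(res.smallest_good_k)]
        assert at_k >= max(res.accuracies) - res.tolerance


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = ConstitutionTripleClassifier(classifier="lda", k=4)
        params = est.get_params()
        assert params["k"] == 4
        est.set_params(k=2)
        assert est.k == 2

    def test_fit_predict_and_question_set(self, separable_triple):
        sub, comb = separable_triple
        est = ConstitutionTripleClassifier(classifier="lda", k=3, item_ids=sub.item_ids)
        est.fit(sub.X.astype(float), sub.y)
        assert sorted(est.question_set_) == [1, 2, 3]
        acc = (est.predict(sub.X.astype(float)) == sub.y).mean()
        assert acc == pytest.approx(1.0)

    def test_works_in_sklearn_cross_val(self, separable_triple):
        from sklearn.model_selection import cross_val_score

        sub, _ = separable_triple
        est = ConstitutionTripleClassifier(classifier="lda", k=3)
        scores = cross_val_score(est, sub.X.astype(float), sub.y, cv=3)
        assert scores.mean() > 0.99


class TestTrainAll:
    def test_registry_of_84_round_trips(self, toy_spec_module, tmp_path):
        ds = build_original_dataset(toy_spec_module, m=6000, seed=5)
        registry = train_all(ds, classifier_kind="lda", k_policy=3, seed=1)
        assert len(registry) == 84
        for m in registry.models.values():
            assert set(m.question_set) <= set(range(1, 10))
            assert len(m.question_set) == 3
        registry.save(tmp_path / "reg")
        again = ModelRegistry.load(tmp_path / "reg")
        assert len(again) == 84
        probe = build_original_dataset(toy_spec_module, m=200, seed=99)
        for idx in (1, 40, 84):
            m1, m2 = registry.models[idx], again.models[idx]
            sub = filter_dataset(probe, m1.combination)
            Xq = project_questions(sub, m1.question_set).X.astype(float)
            assert np.array_equal(m1.predict(Xq), m2.predict(Xq))

    def test_missing_label_aborts(self, toy_spec_module):
        ds = build_original_dataset(toy_spec_module, m=500, seed=5)
        keep = ds.y != int(Constitution.DAMP_HEAT)
        broken = LabeledDataset(ds.X[keep], ds.y[keep], ds.item_ids)
        with pytest.raises(ValueError, match="Damp-heat"):
            train_all(broken, k_policy=3, seed=1)
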