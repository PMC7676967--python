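"""Per-combination identification models: training, cross-validation, sweeps.

For one candidate triple, the identification model is a multiclass
classifier over the triple's three constitution labels, trained on the
chi-squared top-k question columns of the triple's filtered dataset
(``label = classifier(answers on the selected questions)``). This module
provides a scikit-learn estimator for that pipeline, the 5-fold evaluation
panel (mean and best fold accuracy, micro and macro precision/recall/F),
the accuracy-versus-k sweep, and a persistent registry holding one trained
model per combination.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Iterable, Literal, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .combinations import Combination, combination_for, enumerate_combinations, filter_dataset, project_questions
from .constitutions import Constitution
from .datasets import LabeledDataset
from .feature_selection import Chi2Method, DEFAULT_METHOD, chi2_scores, select_top_k
from .synth import child_seed

__all__ = [
    "ClassifierKind",
    "MetricsPanel",
    "CombinationModel",
    "ConstitutionTripleClassifier",
    "make_base_classifier",
    "train_model",
    "cross_validate",
    "sweep_k",
    "train_all",
    "ModelRegistry",
]

ClassifierKind = Literal["lda", "ann", "svm", "rf", "knn"]
N_FOLDS = 5


def make_base_classifier(kind: ClassifierKind, k: int, seed: int = 0):
    """A fresh scikit-learn classifier of the requested kind.

    Hyperparameters are library defaults except where a size must be chosen:
    the neural network gets one hidden layer of ~2k units.
    """
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "ann":
        return MLPClassifier(
            hidden_layer_sizes=(max(4, 2 * k),), max_iter=300, random_state=seed
        )
    if kind == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier()
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclasses.dataclass(frozen=True)
class MetricsPanel:
    """The 5-fold evaluation panel.

    ``accuracy_mean`` averages the fold accuracies; ``accuracy_best`` is the
    highest single fold. Micro metrics pool all fold predictions (for
    single-label multiclass they all equal the pooled accuracy); macro
    metrics average unweighted over the classes. ``response_time_s`` is the
    mean per-fold prediction wall time and is informational only.
    """

    accuracy_mean: float
    accuracy_best: float
    fold_accuracies: tuple[float, ...]
    micro_precision: float
    micro_recall: float
    micro_f: float
    macro_precision: float
    macro_recall: float
    macro_f: float
    response_time_s: float
    folds: int = N_FOLDS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fold_accuracies"] = list(self.fold_accuracies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsPanel":
        d = dict(d)
        d["fold_accuracies"] = tuple(d["fold_accuracies"])
        return cls(**d)


class ConstitutionTripleClassifier(ClassifierMixin, BaseEstimator):
    """Chi-squared top-k question selection + classifier, as one estimator.

    Parameters
    ----------
    classifier : {'lda', 'ann', 'svm', 'rf', 'knn'}, default='lda'
        Kind of downstream classifier.
    k : int, default=16
        Number of questions kept by the chi-squared filter.
    chi2_method : {'feature-sum', 'contingency'}, default='feature-sum'
        Chi-squared variant used for the ranking.
    item_ids : sequence of int or None, default=None
        Item id of each input column; defaults to 1..n_features.
    random_state : int, default=0
        Seed for stochastic classifiers.

    Attributes
    ----------
    classes_ : ndarray
        Constitution ordinals seen in ``y`` (3 for a triple model).
    question_set_ : list of int
        Selected item ids, by descending importance.
    ranking_ : FeatureRanking
        The full chi-squared ranking computed on the training data.
    estimator_ : fitted scikit-learn classifier.
    """

    def __init__(
        self,
        classifier: ClassifierKind = "lda",
        k: int = 16,
        chi2_method: Chi2Method = DEFAULT_METHOD,
        item_ids: Sequence[int] | None = None,
        random_state: int = 0,
    ):
        self.classifier = classifier
        self.k = k
        self.chi2_method = chi2_method
        self.item_ids = item_ids
        self.random_state = random_state

    def _resolve_item_ids(self, n_features: int) -> tuple[int, ...]:
        if self.item_ids is None:
            return tuple(range(1, n_features + 1))
        ids = tuple(int(i) for i in self.item_ids)
        if len(ids) != n_features:
            raise ValueError(
                f"item_ids has {len(ids)} entries for {n_features} columns"
            )
        return ids

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        ids = self._resolve_item_ids(X.shape[1])
        ds = LabeledDataset(X=X, y=y, item_ids=ids)
        self.ranking_ = chi2_scores(ds, method=self.chi2_method)
        self.question_set_ = select_top_k(self.ranking_, self.k)
        self._cols_ = [ids.index(i) for i in self.question_set_]
        self.classes_ = np.unique(y)
        est = make_base_classifier(self.classifier, self.k, self.random_state)
        est.fit(X[:, self._cols_], y)
        self.estimator_ = est
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X = np.asarray(X)
        return self.estimator_.predict(X[:, self._cols_])

    def predict_on_questions(self, X_selected):
        """Predict from answers already restricted to ``question_set_`` order."""
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict(np.asarray(X_selected))


@dataclasses.dataclass
class CombinationModel:
    """A trained identification model for one candidate triple."""

    combination: Combination
    question_set: list[int]
    classifier_kind: str
    estimator: object
    metrics: MetricsPanel
    train_seed: int

    @property
    def k(self) -> int:
        return len(self.question_set)

    def predict(self, answers: np.ndarray) -> np.ndarray:
        """Predict constitutions from an ``(m, k)`` matrix in question_set order."""
        arr = np.asarray(answers)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != self.k:
            raise ValueError(
                f"expected {self.k} answer columns (question set order), "
                f"got {arr.shape[1]}"
            )
        return self.estimator.predict(arr)


def cross_validate(
    dataset: LabeledDataset,
    question_set: Sequence[int],
    classifier_kind: ClassifierKind = "lda",
    folds: int = N_FOLDS,
    seed: int = 0,
) -> MetricsPanel:
    """Stratified k-fold evaluation of a classifier on the given questions.

    The test folds are disjoint and cover the dataset; micro metrics are
    computed on the pooled out-of-fold predictions, macro metrics as the
    unweighted mean over classes.
    """
    proj = project_questions(dataset, question_set)
    X, y = proj.X.astype(np.float64), proj.y
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2:
        raise ValueError("need >= 2 classes for cross-validation")
    if counts.min() < folds:
        lacking = Constitution(int(np.unique(y)[np.argmin(counts)])).label
        raise ValueError(
            f"class {lacking} has {counts.min()} rows, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed & 0x7FFFFFFF)
    accs: list[float] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    pred_time = 0.0
    for f, (tr, te) in enumerate(skf.split(X, y)):
        est = make_base_classifier(
            classifier_kind, len(question_set), child_seed(seed, f"fold{f}")
        )
        est.fit(X[tr], y[tr])
        t0 = time.perf_counter()
        pred = est.predict(X[te])
        pred_time += time.perf_counter() - t0
        accs.append(accuracy_score(y[te], pred))
        pooled_true.append(y[te])
        pooled_pred.append(pred)
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    mi_p, mi_r, mi_f, _ = precision_recall_fscore_support(
        yt, yp, average="micro", zero_division=0
    )
    ma_p, ma_r, ma_f, _ = precision_recall_fscore_support(
        yt, yp, average="macro", zero_division=0
    )
    return MetricsPanel(
        accuracy_mean=float(np.mean(accs)),
        accuracy_best=float(np.max(accs)),
        fold_accuracies=tuple(float(a) for a in accs),
        micro_precision=float(mi_p),
        micro_recall=float(mi_r),
        micro_f=float(mi_f),
        macro_precision=float(ma_p),
        macro_recall=float(ma_r),
        macro_f=float(ma_f),
        response_time_s=pred_time / folds,
    )


def train_model(
    dataset: LabeledDataset,
    question_set: Sequence[int],
    classifier_kind: ClassifierKind = "lda",
    seed: int = 0,
    combination: Combination | None = None,
    folds: int = N_FOLDS,
) -> CombinationModel:
    """Cross-validate, then fit on all rows of a combination's dataset."""
    if dataset.n_samples == 0:
        raise ValueError("cannot train on an empty dataset")
    present = set(dataset.classes())
    if combination is None:
        if len(present) != 3:
            raise ValueError(
                f"dataset has labels {sorted(c.label for c in present)}; "
                "expected exactly a 3-type combination (or pass one explicitly)"
            )
        combination = combination_for(present)
    missing = [c.label for c in combination.members if c not in present]
    if missing:
        raise ValueError(f"no training rows for constitution(s) {missing}")
    metrics = cross_validate(
        dataset, question_set, classifier_kind, folds=folds, seed=seed
    )
    proj = project_questions(dataset, question_set)
    est = make_base_classifier(
        classifier_kind, len(question_set), child_seed(seed, "final")
    )
    est.fit(proj.X.astype(np.float64), proj.y)
    return CombinationModel(
        combination=combination,
        question_set=list(question_set),
        classifier_kind=classifier_kind,
        estimator=est,
        metrics=metrics,
        train_seed=seed,
    )


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Accuracy as a function of k for one combination and classifier."""

    ks: tuple[int, ...]
    accuracies: tuple[float, ...]
    best_k: int           # argmax accuracy (ties to the smaller k)
    smallest_good_k: int  # smallest k within `tolerance` of the maximum
    tolerance: float


def sweep_k(
    dataset: LabeledDataset,
    classifier_kind: ClassifierKind = "lda",
    k_range: Iterable[int] | None = None,
    seed: int = 0,
    chi2_method: Chi2Method = DEFAULT_METHOD,
    tolerance: float = 0.0005,
    folds: int = N_FOLDS,
) -> SweepResult:
    """Cross-validated accuracy for each k over a single chi-squared ranking.

    ``tolerance`` is an accuracy fraction (0.0005 = 0.05 percentage points):
    ``smallest_good_k`` is the smallest k whose mean accuracy is within it
    of the sweep maximum.
    """
    n = len(dataset.item_ids)
    ks = sorted(set(k_range)) if k_range is not None else list(range(1, n + 1))
    if any(k < 1 or k > n for k in ks):
        raise ValueError(f"k values must lie in [1, {n}]")
    ranking = chi2_scores(dataset, method=chi2_method)
    accs = []
    for k in ks:
        qs = select_top_k(ranking, k)
        panel = cross_validate(dataset, qs, classifier_kind, folds=folds, seed=seed)
        accs.append(panel.accuracy_mean)
    accs_arr = np.asarray(accs)
    best_k = ks[int(np.argmax(accs_arr))]
    good = accs_arr >= accs_arr.max() - tolerance
    smallest_good_k = ks[int(np.argmax(good))]
    return SweepResult(
        ks=tuple(ks),
        accuracies=tuple(float(a) for a in accs),
        best_k=best_k,
        smallest_good_k=smallest_good_k,
        tolerance=tolerance,
    )


def _resolve_k(
    dataset: LabeledDataset,
    classifier_kind: ClassifierKind,
    k_policy: int | str,
    seed: int,
    chi2_method: Chi2Method,
    k_grid: Iterable[int] | None,
    folds: int,
) -> int:
    if isinstance(k_policy, int):
        return k_policy
    if k_policy == "auto":
        grid = k_grid if k_grid is not None else range(2, len(dataset.item_ids) + 1, 2)
        sweep = sweep_k(
            dataset, classifier_kind, grid, seed=seed,
            chi2_method=chi2_method, folds=folds,
        )
        return sweep.smallest_good_k
    raise ValueError(f"k_policy must be an int or 'auto', got {k_policy!r}")


def train_all(
    original_dataset: LabeledDataset,
    classifier_kind: ClassifierKind = "lda",
    k_policy: int | str = "auto",
    seed: int = 0,
    chi2_method: Chi2Method = DEFAULT_METHOD,
    k_grid: Iterable[int] | None = None,
    folds: int = N_FOLDS,
) -> "ModelRegistry":
    """Train one model per candidate triple (84 in all).

    ``k_policy`` is either a fixed question count or ``'auto'``: sweep k and
    keep the smallest k within 0.05 percentage points of the maximum
    accuracy. Any combination that cannot be trained (a constitution with no
    rows) aborts with an error naming the combination.
    """
    present = set(original_dataset.classes())
    missing = [c.label for c in Constitution if c not in present]
    if missing:
        raise ValueError(f"original dataset lacks label(s) {missing}")
    models: dict[int, CombinationModel] = {}
    for comb in enumerate_combinations():
        sub = filter_dataset(original_dataset, comb)
        cseed = child_seed(seed, f"comb{comb.index}")
        try:
            ranking = chi2_scores(sub, method=chi2_method)
            k = _resolve_k(
                sub, classifier_kind, k_policy, cseed, chi2_method, k_grid, folds
            )
            qs = select_top_k(ranking, k)
            models[comb.index] = train_model(
                sub, qs, classifier_kind, seed=cseed, combination=comb, folds=folds
            )
        except ValueError as exc:
            raise ValueError(f"training failed for combination {comb}: {exc}") from exc
    return ModelRegistry(models)


class ModelRegistry:
    """The 84 trained combination models, addressable by triple.

    Persists as a directory: ``registry.json`` (combination indices and
    member names, question ids, classifier kind, metrics, seeds) plus one
    joblib payload per model.
    """

    def __init__(self, models: dict[int, CombinationModel]):
        self.models = dict(models)

    def __len__(self) -> int:
        return len(self.models)

    def get(self, members: Iterable[Constitution | str]) -> CombinationModel:
        comb = combination_for(members)
        try:
            return self.models[comb.index]
        except KeyError:
            raise KeyError(f"no trained model for combination {comb}") from None

    def manifest(self) -> dict:
        return {
            "n_models": len(self.models),
            "combinations": [
                {
                    "index": m.combination.index,
                    "members": list(m.combination.names),
                    "question_ids": list(m.question_set),
                    "classifier": m.classifier_kind,
                    "train_seed": m.train_seed,
                    "metrics": m.metrics.to_dict(),
                }
                for m in sorted(self.models.values(), key=lambda m: m.combination.index)
            ],
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "registry.json").write_text(
            json.dumps(self.manifest(), indent=1)
        )
        for idx, model in self.models.items():
            joblib.dump(model.estimator, directory / f"model_{idx:03d}.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelRegistry":
        directory = Path(directory)
        manifest = json.loads((directory / "registry.json").read_text())
        models: dict[int, CombinationModel] = {}
        for entry in manifest["combinations"]:
            comb = combination_for(entry["members"])
            est = joblib.load(directory / f"model_{entry['index']:03d}.joblib")
            models[entry["index"]] = CombinationModel(
                combination=comb,
                question_set=list(entry["question_ids"]),
                classifier_kind=entry["classifier"],
                estimator=est,
                metrics=MetricsPanel.from_dict(entry["metrics"]),
                train_seed=entry["train_seed"],
            )
        return cls(models)
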