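"""Registry of base classifiers and the hybrid RF-SVM double classifier.

All models sit behind one fit/predict contract: ``fit`` takes a
:class:`~gasselect.data_model.Dataset`, ``predict`` takes a feature matrix and
returns a :class:`PredictionSet` whose probability rows sum to one and whose
labels are the probability argmax (ties broken by class order).

The double classifier soft-votes: it averages the Random-Forest and the
probability-calibrated SVM class probabilities elementwise (a stacking variant
is available via ``hyperparams={"combine": "stack"}``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import Dataset, SplitPair
from .exceptions import DegenerateTrainingError, RegistryError, SchemaError

__all__ = [
    "ClassifierSpec",
    "PredictionSet",
    "REGISTRY_NAMES",
    "make_classifier",
    "rf_svm_predict",
    "fit_predict",
]

REGISTRY_NAMES = ("knn", "rf", "c45", "ann", "svm", "rf_svm")


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameters + seed for one model."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in REGISTRY_NAMES:
            raise RegistryError(
                f"unknown classifier {self.name!r}; valid names: {list(REGISTRY_NAMES)}"
            )


@dataclass
class PredictionSet:
    """Predicted labels with per-class probabilities (rows sum to 1)."""

    labels: np.ndarray
    probabilities: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        rows = self.probabilities.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            self.probabilities = self.probabilities / rows[:, None]


class _RfSvmEnsemble:
    """Soft-voting (or stacking) combination of RF and calibrated SVM."""

    def __init__(self, hyperparams: dict, seed: int):
        self.combine = hyperparams.get("combine", "vote")
        self.rf = RandomForestClassifier(
            n_estimators=hyperparams.get("n_estimators", 100), random_state=seed
        )
        self.svm = SVC(
            kernel=hyperparams.get("kernel", "rbf"), probability=True, random_state=seed
        )
        self.seed = seed

    def fit(self, X, y):
        self.rf.fit(X, y)
        if self.combine == "stack":
            # out-of-fold RF probabilities become the SVM's inputs
            oof = cross_val_predict(
                RandomForestClassifier(
                    n_estimators=self.rf.n_estimators, random_state=self.seed
                ),
                X,
                y,
                cv=3,
                method="predict_proba",
            )
            self.svm.fit(oof, y)
            self.classes_ = self.svm.classes_
        else:
            self.svm.fit(X, y)
            self.classes_ = self.rf.classes_
        return self

    def predict_proba(self, X):
        rf_p = self.rf.predict_proba(X)
        if self.combine == "stack":
            return self.svm.predict_proba(rf_p)
        return (rf_p + self.svm.predict_proba(X)) / 2.0


def _build(spec: ClassifierSpec):
    h, seed = spec.hyperparams, spec.seed
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=h.get("k", 5))
    if spec.name == "rf":
        return RandomForestClassifier(
            n_estimators=h.get("n_estimators", 100), random_state=seed
        )
    if spec.name == "c45":
        # entropy splitting reflects the C4.5 information-gain lineage
        return DecisionTreeClassifier(
            criterion="entropy", max_depth=h.get("max_depth"), random_state=seed
        )
    if spec.name == "ann":
        return MLPClassifier(
            hidden_layer_sizes=h.get("hidden_layer_sizes", (64,)),
            early_stopping=h.get("early_stopping", True),
            max_iter=h.get("max_iter", 300),
            random_state=seed,
        )
    if spec.name == "svm":
        return SVC(kernel=h.get("kernel", "rbf"), probability=True, random_state=seed)
    return _RfSvmEnsemble(h, seed)


class ClassifierHandle:
    """Uniform fit/predict wrapper around one registry model."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.model = _build(spec)
        self.feature_names: list[str] | None = None

    def fit(self, train: Dataset) -> "ClassifierHandle":
        present = np.unique(train.labels.astype(str))
        if present.size < 2:
            raise DegenerateTrainingError(
                f"training data has a single class {present.tolist()}"
            )
        self.model.fit(train.features, train.labels.astype(str))
        self.feature_names = list(train.feature_names)
        return self

    def predict(self, features: np.ndarray) -> PredictionSet:
        proba = self.model.predict_proba(np.asarray(features, dtype=float))
        classes = [str(c) for c in self.model.classes_]
        labels = np.asarray(classes, dtype=object)[np.argmax(proba, axis=1)]
        return PredictionSet(labels, proba, classes)


def make_classifier(spec: ClassifierSpec) -> ClassifierHandle:
    """Build a handle for one of {knn, rf, c45, ann, svm, rf_svm}."""
    return ClassifierHandle(spec)


def rf_svm_predict(
    train: Dataset, test_features: np.ndarray, spec: ClassifierSpec | None = None
) -> PredictionSet:
    """Fit the double classifier on ``train`` and predict ``test_features``."""
    spec = spec or ClassifierSpec("rf_svm")
    if spec.name != "rf_svm":
        raise RegistryError("rf_svm_predict requires spec.name == 'rf_svm'")
    return make_classifier(spec).fit(train).predict(test_features)


def fit_predict(spec: ClassifierSpec, split: SplitPair) -> PredictionSet:
    """Convenience: fit on the train half, predict the test half."""
    if split.train.feature_names != split.test.feature_names:
        raise SchemaError("train/test halves disagree on the feature schema")
    return make_classifier(spec).fit(split.train).predict(split.test.features)
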