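"""Classifier training, selection and evaluation for the six curve classes.

Five families are compared -- support-vector (SVC), logistic regression
(LRC), k-nearest neighbors (kNN), decision tree (DTC) and linear
discriminant analysis (LDA) -- via an exhaustive grid search with stratified
5-fold cross-validation on the 70% training split; metrics are
macro-averaged, and the confusion matrix uses rows = true, columns =
predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocess import NormalizerState, normalize_apply
from .simgen import CurveClass, FluorescenceCurve, Group, LabeledDataset

__all__ = [
    "CLASS_LABELS",
    "SplitSpec",
    "ModelSpec",
    "EvalReport",
    "DEFAULT_SPECS",
    "split_dataset",
    "grid_search",
    "train_final",
    "evaluate",
    "predict_curve",
    "save_model",
    "load_model",
]

CLASS_LABELS = [c.value for c in CurveClass]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    family: str
    grid: tuple[dict, ...]
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in _FACTORIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {sorted(_FACTORIES)}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _make_svc(p):
    return SVC(**p)


def _make_lrc(p):
    return LogisticRegression(max_iter=5000, **p)


def _make_knn(p):
    return KNeighborsClassifier(**p)


def _make_dtc(p):
    return DecisionTreeClassifier(random_state=0, **p)


def _make_lda(p):
    return LinearDiscriminantAnalysis(**p)


_FACTORIES = {
    "SVC": _make_svc,
    "LRC": _make_lrc,
    "kNN": _make_knn,
    "DTC": _make_dtc,
    "LDA": _make_lda,
}

# Small exhaustive grids; the SVC grid contains the reference optimum
# (C=0.5, RBF kernel, gamma=1).
DEFAULT_SPECS: dict[str, ModelSpec] = {
    "SVC": ModelSpec(
        "SVC",
        (
            {"kernel": ["rbf"], "C": [0.1, 0.5, 1, 10], "gamma": [0.1, 0.5, 1, "scale"]},
            {"kernel": ["linear"], "C": [0.1, 0.5, 1, 10]},
        ),
    ),
    "LRC": ModelSpec("LRC", ({"C": [0.1, 1, 10]},)),
    "kNN": ModelSpec("kNN", ({"n_neighbors": [1, 3, 5, 7]},)),
    "DTC": ModelSpec("DTC", ({"max_depth": [3, 5, 10, None]},)),
    "LDA": ModelSpec("LDA", ({},)),
}


@dataclass(frozen=True)
class EvalReport:
    """Macro-averaged metrics and 6x6 confusion (rows true, cols predicted)."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    confusion: np.ndarray
    labels: tuple[str, ...] = field(default=tuple(CLASS_LABELS))

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
        }


def split_dataset(
    ds: LabeledDataset, spec: SplitSpec | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic (stratified) train/test split; disjoint and exhaustive."""
    if spec is None:
        spec = SplitSpec()
    n = len(ds)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    labels = ds.labels()
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        for lab in sorted(set(labels)):
            members = np.nonzero(labels == lab)[0]
            if len(members) < 2:
                raise ValueError(
                    f"class {lab!r} has fewer than 2 samples; cannot stratify"
                )
            perm = members[rng.permutation(len(members))]
            n_train = int(round(spec.train_fraction * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            train_idx.extend(perm[:n_train].tolist())
            test_idx.extend(perm[n_train:].tolist())
    else:
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        train_idx = perm[:n_train].tolist()
        test_idx = perm[n_train:].tolist()
    train_idx.sort()
    test_idx.sort()
    return ds.subset(train_idx), ds.subset(test_idx)


def _features_labels(
    ds: LabeledDataset, normalizer: NormalizerState | None
) -> tuple[np.ndarray, np.ndarray]:
    X = ds.feature_matrix()
    if normalizer is not None:
        X = normalizer.transform(X)
    return X, ds.labels()


def grid_search(
    spec: ModelSpec,
    train: LabeledDataset,
    normalizer: NormalizerState | None = None,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive grid search with stratified k-fold CV on the training split.

    Returns ``(best_params, mean_cv_accuracy)``; ties are broken by grid
    enumeration order.
    """
    X, y = _features_labels(train, normalizer)
    _, counts = np.unique(y, return_counts=True)
    if spec.cv_folds > counts.min():
        raise ValueError(
            f"cv_folds={spec.cv_folds} exceeds the smallest class count {counts.min()}"
        )
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    best_params: dict | None = None
    best_score = -np.inf
    for params in ParameterGrid(list(spec.grid)):
        scores = []
        for tr, va in folds:
            model = _FACTORIES[spec.family](params)
            model.fit(X[tr], y[tr])
            scores.append(float(np.mean(model.predict(X[va]) == y[va])))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:  # strict: first grid point wins ties
            best_score = mean_score
            best_params = params
    assert best_params is not None
    return best_params, best_score


def train_final(family: str, params: dict, train: LabeledDataset, normalizer: NormalizerState | None = None):
    """Fit the chosen family/hyperparameters on the full training split."""
    X, y = _features_labels(train, normalizer)
    model = _FACTORIES[family](params)
    model.fit(X, y)
    return model


def save_model(model, path) -> None:
    joblib.dump(model, path)


def load_model(path):
    return joblib.load(path)


def evaluate(
    model, test: LabeledDataset, normalizer: NormalizerState | None = None
) -> EvalReport:
    """Held-out evaluation: macro precision/recall/F1, accuracy, confusion."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    X, y_true = _features_labels(test, normalizer)
    unknown = set(y_true) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"labels outside the six classes: {sorted(unknown)}")
    y_pred = model.predict(X)
    k = len(CLASS_LABELS)
    index = {lab: i for i, lab in enumerate(CLASS_LABELS)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    tp = np.diag(confusion).astype(float)
    row = confusion.sum(axis=1).astype(float)  # true counts
    col = confusion.sum(axis=0).astype(float)  # predicted counts
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(col > 0, tp / col, 0.0)
        rec_c = np.where(row > 0, tp / row, 0.0)
        f1_c = np.where(
            prec_c + rec_c > 0, 2 * prec_c * rec_c / (prec_c + rec_c), 0.0
        )
    return EvalReport(
        precision=float(prec_c.mean()),
        recall=float(rec_c.mean()),
        accuracy=float(tp.sum() / confusion.sum()),
        f1=float(f1_c.mean()),
        confusion=confusion,
    )


def predict_curve(
    model, normalizer: NormalizerState, curve: FluorescenceCurve
) -> tuple[CurveClass, Group]:
    """Six-way label and its three-way group for a single curve."""
    z = normalize_apply(normalizer, curve)
    label = CurveClass.from_label(str(model.predict(z.reshape(1, -1))[0]))
    return label, label.group
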