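"""Binary preictal/interictal classification behind a small contract.

The reference classifier is a support vector machine with an RBF
kernel.  Its cost C and kernel width g are chosen by an exhaustive grid
search maximising mean accuracy under stratified k-fold (default
six-fold) cross-validation of the balanced training set; ties prefer
the smaller C, then the smaller g (the least complex model).  Anything
exposing ``fit(X, y)`` / ``predict(X)`` on real matrices can be swapped
in through :class:`TrainedModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset_builder import LabeledDataset
from .errors import ValidationError
from .ordinal_entropy import FeatureSeries

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "DEFAULT_C_GRID",
    "DEFAULT_G_GRID",
    "grid_search_cv",
    "train",
    "predict_labels",
]

# Standard exponential search ranges: C = 2^-5 .. 2^15, g = 2^-15 .. 2^3.
DEFAULT_C_GRID: Tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_G_GRID: Tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class ModelSpec:
    """RBF-SVM hyper-parameters (cost C, kernel width g)."""

    C: float
    g: float
    kernel: str = "RBF"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g <= 0:
            raise ValidationError(f"C and g must be positive, got C={self.C}, g={self.g}")


@dataclass
class TrainedModel:
    """A fitted decision function plus the spec and training metadata."""

    spec: ModelSpec
    estimator: object
    n_features: int
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature dimensionality {X.shape[1]} != training dimensionality {self.n_features}"
            )
        return self.estimator.predict(X).astype(int)


def _check_two_class(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("training data must contain both classes")


def grid_search_cv(
    train_set: LabeledDataset,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    g_grid: Sequence[float] = DEFAULT_G_GRID,
    folds: int = 6,
    seed: int = 0,
) -> ModelSpec:
    """Pick (C, g) maximising mean stratified-CV accuracy.

    The grid is scanned in ascending (C, g) order and only a strictly
    better mean accuracy replaces the incumbent, so ties resolve to the
    smallest C then smallest g.  Fold assignment is deterministic for a
    given seed.
    """
    _check_two_class(train_set.labels)
    if folds < 2:
        raise ValidationError("need at least 2 CV folds")
    n_min = int(np.bincount(train_set.labels, minlength=2).min())
    if n_min < folds:
        raise ValidationError(
            f"minority class has {n_min} samples, fewer than {folds} folds"
        )
    X, y = train_set.features, train_set.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_spec, best_acc = None, -np.inf
    for C in sorted(set(float(c) for c in C_grid)):
        for g in sorted(set(float(v) for v in g_grid)):
            accs = []
            for tr_idx, va_idx in splits:
                clf = SVC(C=C, gamma=g, kernel="rbf")
                clf.fit(X[tr_idx], y[tr_idx])
                accs.append(np.mean(clf.predict(X[va_idx]) == y[va_idx]))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_acc, best_spec = acc, ModelSpec(C=C, g=g)
    assert best_spec is not None
    return best_spec


def train(spec: ModelSpec, train_set: LabeledDataset) -> TrainedModel:
    """Fit the RBF-SVM with the given spec on the full training set."""
    _check_two_class(train_set.labels)
    clf = SVC(C=spec.C, gamma=spec.g, kernel="rbf")
    clf.fit(train_set.features, train_set.labels)
    return TrainedModel(
        spec=spec,
        estimator=clf,
        n_features=train_set.features.shape[1],
        metadata={"n_train": train_set.n_samples},
    )


def predict_labels(model: TrainedModel, fs: FeatureSeries) -> np.ndarray:
    """One binary label per feature window (1 = preictal, 0 = interictal)."""
    return model.predict(fs.values.T)
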