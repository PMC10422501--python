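"""One-vs-all linear SVM classification and leave-one-person-out evaluation.

Training uses the liblinear solver (through scikit-learn's ``LinearSVC``)
with misclassification cost C = 1 by default; features are expected to be
L2-normalised clip descriptors.  Prediction takes the argmax of the
per-class decision values, with exact ties broken by class order (the
manifest's sorted label order).

Evaluation follows the leave-one-person-out (LOPO) protocol: each subject's
clips form one test fold and all other subjects' clips train the model;
predictions are accumulated into a single pooled confusion matrix from
which accuracy, per-class precision and average per-class precision (AP)
are computed:

    accuracy (%)  = 100 * sum_i C_ii / N
    Pre(j) (%)    = 100 * C_jj / sum_i C_ij       (0 if column j is empty)
    AP (%)        = (100 / N_c) * sum_j Pre(j)

with C_ij the count of clips of true class i predicted as class j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .errors import DataError, ParameterError, TrainingError
from .manifest_io import DatasetManifest

logger = logging.getLogger(__name__)


@dataclass
class OvRModel:
    """Per-class linear scorers (weights + bias) in fixed class order."""

    classes: tuple[str, ...]
    weights: np.ndarray  # (n_classes, n_features); one row per binary scorer
    biases: np.ndarray  # (n_classes,)
    cost: float

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


def train_ovr(
    features: np.ndarray,
    labels: Sequence[str],
    cost: float = 1.0,
    seed: int = 0,
    tol: float = 1e-4,
) -> OvRModel:
    """Fit one binary linear SVM per class (one-vs-all) with liblinear."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ParameterError(f"feature matrix must be 2-D, got {features.shape}")
    if not np.all(np.isfinite(features)):
        raise DataError("feature matrix contains non-finite values")
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise TrainingError(
            f"training requires at least 2 classes, got {len(classes)}"
        )
    svc = LinearSVC(C=cost, tol=tol, random_state=seed, max_iter=10000, dual="auto")
    svc.fit(features, labels)
    order = [list(svc.classes_).index(c) for c in classes]
    coef = svc.coef_
    intercept = svc.intercept_
    if len(classes) == 2:
        # sklearn fits a single separating function for 2 classes; expand it
        # into the two symmetric one-vs-rest scorers
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
        order = [0, 1]
    return OvRModel(
        classes=classes,
        weights=coef[order].astype(np.float64),
        biases=intercept[order].astype(np.float64),
        cost=cost,
    )


def decision_values(model: OvRModel, features: np.ndarray) -> np.ndarray:
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != model.n_features:
        raise ParameterError(
            f"feature length {features.shape[1]} does not match model "
            f"dimension {model.n_features}"
        )
    return features @ model.weights.T + model.biases


def predict(model: OvRModel, features: np.ndarray) -> np.ndarray:
    """Argmax of the per-class decision values; ties go to the earlier class."""
    scores = decision_values(model, features)
    # np.argmax returns the first maximum, which is the documented tie rule
    indices = np.argmax(scores, axis=1)
    return np.asarray([model.classes[i] for i in indices])


@dataclass
class ConfusionMatrix:
    """Pooled counts; row = ground-truth class, column = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ParameterError(
                f"confusion matrix shape {self.counts.shape} does not match "
                f"{n} classes"
            )
        if np.any(self.counts < 0):
            raise DataError("confusion matrix counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def add(self, truths: Sequence[str], predictions: Sequence[str]) -> None:
        index = {c: i for i, c in enumerate(self.classes)}
        for truth, prediction in zip(truths, predictions, strict=True):
            self.counts[index[truth], index[prediction]] += 1

    @classmethod
    def empty(cls, classes: Sequence[str]) -> "ConfusionMatrix":
        classes = tuple(classes)
        return cls(np.zeros((len(classes), len(classes)), dtype=np.int64), classes)


def accuracy(confusion: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / N."""
    total = confusion.n_samples
    if total == 0:
        raise ParameterError("confusion matrix is empty")
    return 100.0 * float(np.trace(confusion.counts)) / total


def per_class_precision(confusion: ConfusionMatrix) -> np.ndarray:
    """Pre(j) = 100 * C_jj / column sum j, with 0 for never-predicted classes."""
    counts = confusion.counts.astype(np.float64)
    column_sums = counts.sum(axis=0)
    precision = np.zeros(len(confusion.classes))
    predicted = column_sums > 0
    precision[predicted] = 100.0 * np.diag(counts)[predicted] / column_sums[predicted]
    for j in np.nonzero(~predicted)[0]:
        logger.info(
            "class %r was never predicted; Pre set to 0 by convention",
            confusion.classes[j],
        )
    return precision


def average_precision(confusion: ConfusionMatrix) -> float:
    """AP: unweighted mean of the per-class precisions, in percent."""
    return float(per_class_precision(confusion).mean())


@dataclass
class FoldRecord:
    subject_id: str
    n_train: int
    n_test: int
    accuracy: float


@dataclass
class EvaluationResult:
    """LOPO outcome: pooled confusion matrix, metrics and per-fold log."""

    confusion: ConfusionMatrix
    accuracy: float
    per_class_precision: np.ndarray
    average_precision: float
    fold_log: list[FoldRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.confusion.classes),
            "confusion_matrix": self.confusion.counts.tolist(),
            "accuracy_percent": self.accuracy,
            "per_class_precision_percent": self.per_class_precision.tolist(),
            "average_precision_percent": self.average_precision,
            "folds": [
                {
                    "subject_id": f.subject_id,
                    "n_train": f.n_train,
                    "n_test": f.n_test,
                    "accuracy_percent": f.accuracy,
                }
                for f in self.fold_log
            ],
        }


def lopo_evaluate(
    manifest: DatasetManifest,
    features: Mapping[str, np.ndarray],
    cost: float = 1.0,
    seed: int = 0,
    skip_single_class_folds: bool = False,
) -> EvaluationResult:
    """Leave-one-person-out cross-validation over precomputed clip features.

    ``features`` maps each clip_id to its (normalised) descriptor.  One fold
    is run per subject; every clip is predicted exactly once and the
    confusion matrix is pooled across folds.
    """
    if len(manifest.subjects) < 2:
        raise ParameterError("LOPO needs at least 2 subjects")
    if len(manifest.classes) < 2:
        raise ParameterError("classification needs at least 2 classes")
    missing = [r.clip_id for r in manifest.records if r.clip_id not in features]
    if missing:
        raise ParameterError(f"missing features for clips: {missing[:5]}")

    confusion = ConfusionMatrix.empty(manifest.classes)
    fold_log: list[FoldRecord] = []
    for subject in manifest.subjects:
        test = [r for r in manifest.records if r.subject_id == subject]
        train = [r for r in manifest.records if r.subject_id != subject]
        assert all(r.subject_id != subject for r in train), "subject leakage"
        train_labels = [r.label for r in train]
        if len(set(train_labels)) < 2:
            message = (
                f"fold {subject!r}: training set has a single class; "
                + ("skipped" if skip_single_class_folds else "aborting")
            )
            logger.error(message)
            if skip_single_class_folds:
                continue
            raise TrainingError(message)
        model = train_ovr(
            np.vstack([features[r.clip_id] for r in train]),
            train_labels,
            cost=cost,
            seed=seed,
        )
        predictions = predict(
            model, np.vstack([features[r.clip_id] for r in test])
        )
        truths = [r.label for r in test]
        confusion.add(truths, predictions)
        fold_correct = sum(t == p for t, p in zip(truths, predictions))
        fold_log.append(
            FoldRecord(
                subject_id=subject,
                n_train=len(train),
                n_test=len(test),
                accuracy=100.0 * fold_correct / len(test),
            )
        )
    return EvaluationResult(
        confusion=confusion,
        accuracy=accuracy(confusion),
        per_class_precision=per_class_precision(confusion),
        average_precision=average_precision(confusion),
        fold_log=fold_log,
    )
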