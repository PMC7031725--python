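"""House-Brackmann grade classifiers and patient-grouped cross-validation.

Three classifiers operate on the 14-element relative regional flow vector:

* K-NN with Euclidean distance and k = 11; the likelihood is the vote
  fraction among the neighbors.
* SVM with a polynomial kernel of degree 2; one-vs-rest decision values are
  mapped through a softmax to obtain a six-grade likelihood.
* A feed-forward network 14 -> 32 -> 16 -> 6 with rectifier activations and
  a cross-entropy objective, trained full-batch.

Each prediction is a likelihood vector over the six HB grades (index 0 ->
grade I ... index 5 -> grade VI) summing to one; the predicted grade is the
argmax, with exact ties broken toward the lower (less severe) grade.

Cross-validation shuffles and partitions at the patient level, so no
patient's data can appear in both a training and a validation fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateTrainingError, ValidationError
from .perfusion_features import FeatureVector

logger = logging.getLogger(__name__)

N_GRADES = 6
N_FEATURES = 14
KINDS = ("knn", "svm", "nn")


@dataclass
class ClassifierSpec:
    """Configuration of one HB-score classifier.

    Defaults follow the reference settings: k-NN with Euclidean distance and
    k = 11; SVM with a degree-2 polynomial kernel; a network with two hidden
    layers.  Standardization (zero mean / unit variance, fitted on training
    data only) defaults to on for svm/nn and off for knn.
    """

    kind: str = "nn"
    knn_k: int = 11
    svm_degree: int = 2
    nn_hidden: tuple = (32, 16)
    nn_alpha: float = 0.1
    epochs: int = 500
    standardize: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown classifier kind {self.kind!r}; expected {KINDS}")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.svm_degree != 2:
            raise ValidationError("the SVM kernel is a polynomial of degree 2")
        if len(self.nn_hidden) != 2:
            raise ValidationError("the network has exactly two hidden layers")
        if self.nn_alpha < 0:
            raise ValidationError("nn_alpha must be nonnegative")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")

    @property
    def use_scaler(self) -> bool:
        return self.kind in ("svm", "nn") if self.standardize is None else self.standardize


def _as_matrix(features) -> np.ndarray:
    rows = []
    for f in features:
        if isinstance(f, FeatureVector):
            rows.append(f.values)
        else:
            arr = np.asarray(f, dtype=float)
            if arr.shape != (N_FEATURES,):
                raise ValidationError(
                    f"each feature must have {N_FEATURES} entries, got {arr.shape}"
                )
            rows.append(arr)
    return np.asarray(rows, dtype=float)


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    estimator: object
    scaler: StandardScaler | None
    classes: np.ndarray  # grades present in training, sorted ascending
    seed: int | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X) if self.scaler is not None else X


def train(spec: ClassifierSpec, features, grades, seed: int | None = None) -> TrainedClassifier:
    """Fit one classifier; deterministic given (spec, data, seed)."""
    X = _as_matrix(features)
    y = np.asarray(grades, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError(
            f"feature/label count mismatch: {X.shape[0]} vs {y.shape[0]}"
        )
    if y.size == 0:
        raise ValidationError("empty training set")
    if np.any((y < 1) | (y > N_GRADES)):
        raise ValidationError("HB grades must lie in 1-6")
    classes = np.unique(y)
    if spec.kind in ("svm", "nn") and classes.size < 2:
        raise DegenerateTrainingError(
            f"{spec.kind} training requires at least 2 classes, found {classes.size}"
        )
    if spec.kind == "knn" and spec.knn_k > y.size:
        raise ValidationError(
            f"knn_k={spec.knn_k} exceeds training set size {y.size}"
        )
    scaler = None
    Xt = X
    if spec.use_scaler:
        scaler = StandardScaler().fit(X)
        Xt = scaler.transform(X)
    if spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    elif spec.kind == "svm":
        est = SVC(
            kernel="poly",
            degree=spec.svm_degree,
            coef0=1.0,
            gamma="scale",
            decision_function_shape="ovr",
            random_state=seed,
        )
    else:
        est = MLPClassifier(
            hidden_layer_sizes=tuple(spec.nn_hidden),
            activation="relu",
            solver="lbfgs",  # full-batch quasi-Newton; fast on cohort-sized data
            alpha=spec.nn_alpha,
            max_iter=spec.epochs,
            random_state=seed,
        )
    est.fit(Xt, y)
    return TrainedClassifier(spec=spec, estimator=est, scaler=scaler, classes=classes, seed=seed)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_likelihood(clf: TrainedClassifier, feature) -> np.ndarray:
    """Six-grade likelihood vector (simplex within 1e-9)."""
    if isinstance(feature, FeatureVector):
        x = feature.values
    else:
        x = np.asarray(feature, dtype=float)
    if x.shape != (N_FEATURES,):
        raise ValidationError(f"feature must have {N_FEATURES} entries, got {x.shape}")
    Xt = clf._transform(x[None, :])
    if clf.spec.kind == "svm":
        df = np.atleast_1d(np.asarray(clf.estimator.decision_function(Xt)).squeeze())
        if clf.classes.size == 2:  # binary decision value -> two margins
            df = np.array([-df.item(), df.item()])
        probs = _softmax(df)
    else:
        probs = clf.estimator.predict_proba(Xt)[0]
    out = np.zeros(N_GRADES)
    out[clf.classes - 1] = probs
    total = out.sum()
    if total <= 0:
        raise ValidationError("degenerate likelihood output")
    return out / total


def predict_grade(clf: TrainedClassifier, feature) -> int:
    """Argmax grade; exact likelihood ties break toward the lower grade."""
    lik = predict_likelihood(clf, feature)
    best = int(np.argmax(lik))  # argmax returns the first (lowest) maximum
    if np.sum(lik == lik[best]) > 1:
        logger.info("likelihood tie at %.6f; returning the lower grade %d", lik[best], best + 1)
    return best + 1


@dataclass
class CVReport:
    """Patient-grouped k-fold cross-validation summary."""

    k: int
    fold_accuracies: list
    confusion: np.ndarray  # (6, 6), rows = true grade, cols = predicted
    fold_assignment: dict  # patient_id -> fold index
    predictions: dict = field(default_factory=dict)  # patient_id -> (true, predicted)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "fold_assignment": {str(p): int(f) for p, f in self.fold_assignment.items()},
            "predictions": {
                str(p): {"true": int(t), "predicted": int(e)}
                for p, (t, e) in self.predictions.items()
            },
        }


def grouped_kfold_cv(spec: ClassifierSpec, dataset, k: int, seed: int) -> CVReport:
    """k-fold cross-validation with folds drawn at the patient level.

    ``dataset`` is a sequence of records exposing ``patient_id``,
    ``hb_grade`` and ``features`` (a FeatureVector or 14-vector); each record
    is one sample, so holding out a fold removes every frame of its patients
    from training by construction.
    """
    records = list(dataset)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(records) < k:
        raise ValidationError(f"k={k} exceeds the {len(records)} available patients")
    ids = [str(r.patient_id) for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate patient ids in dataset")
    X = _as_matrix([r.features for r in records])
    y = np.asarray([int(r.hb_grade) for r in records])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    folds = np.array_split(perm, k)
    fold_assignment = {}
    fold_accuracies = []
    confusion = np.zeros((N_GRADES, N_GRADES), dtype=np.int64)
    predictions = {}
    for fold_idx, test_idx in enumerate(folds):
        for i in test_idx:
            fold_assignment[ids[i]] = fold_idx
        train_idx = np.setdiff1d(perm, test_idx)
        clf = train(spec, X[train_idx], y[train_idx], seed=seed)
        correct = 0
        for i in test_idx:
            pred = predict_grade(clf, X[i])
            predictions[ids[i]] = (int(y[i]), pred)
            confusion[y[i] - 1, pred - 1] += 1
            correct += int(pred == y[i])
        fold_accuracies.append(correct / len(test_idx))
    return CVReport(
        k=k,
        fold_accuracies=fold_accuracies,
        confusion=confusion,
        fold_assignment=fold_assignment,
        predictions=predictions,
    )
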