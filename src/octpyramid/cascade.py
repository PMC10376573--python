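"""Two-stage diagnostic cascade over fused pyramid features.

Stage 1 is a binary normal-vs-abnormal decision; samples called abnormal are
passed to stage 2, which separates the disease classes (CNV / DME / DRUSEN).
An all-at-once four-class head over the same features is available for
comparison. Six interchangeable classifier heads are supported — MLP, LR,
SVM, DT, RF, NB — built on scikit-learn with these defaults:

* SVM: RBF kernel, one-vs-rest decision function
* DT: gini criterion, best splitter
* RF: gini criterion, 100 trees
* NB: Gaussian, no priors, variance smoothing 1e-9
* LR: liblinear solver
* MLP: hidden layers (256, 128), ReLU, Adam with initial learning rate
  0.001, 50 epochs, batch size 128

Features are standardised (zero mean, unit variance, fit on the training
data only) for the scale-sensitive heads (MLP, LR, SVM) and used raw for the
tree/Bayes heads. Cascade gating: a sample is labelled ``NORMAL`` iff the
stage-1 abnormal score is below the decision threshold (default 0.5); no
sample gated as normal ever receives a disease label. Ties in the stage-2
argmax break toward the lowest class index (alphabetical: CNV < DME <
DRUSEN), which keeps prediction deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ClassifierSpec", "make_head", "CascadeClassifier",
           "train_stage1", "train_stage2", "train_all_at_once",
           "predict_cascade", "CLASSIFIER_KINDS", "ABNORMAL_CLASSES",
           "NORMAL_LABEL"]

CLASSIFIER_KINDS = ("MLP", "LR", "SVM", "DT", "RF", "NB")
NORMAL_LABEL = "NORMAL"
ABNORMAL_CLASSES = ("CNV", "DME", "DRUSEN")
_STANDARDIZED = {"MLP", "LR", "SVM"}


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """A classifier head choice plus hyperparameter overrides."""

    kind: str = "MLP"
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "kind", str(self.kind).upper())
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind '{self.kind}'; expected one of "
                f"{CLASSIFIER_KINDS}")


def make_head(spec: ClassifierSpec):
    """Build the (unfitted) scikit-learn estimator for a spec.

    Scale-sensitive kinds are wrapped in a standardising pipeline.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind == "MLP":
        est = MLPClassifier(hidden_layer_sizes=(256, 128), activation="relu",
                            solver="adam", learning_rate_init=0.001,
                            max_iter=50, batch_size=128,
                            random_state=spec.seed, **hp)
    elif spec.kind == "LR":
        # liblinear is binary-only; explicit one-vs-rest handles multiclass
        est = OneVsRestClassifier(
            LogisticRegression(solver="liblinear", random_state=spec.seed, **hp))
    elif spec.kind == "SVM":
        est = SVC(kernel="rbf", decision_function_shape="ovr",
                  random_state=spec.seed, **hp)
    elif spec.kind == "DT":
        est = DecisionTreeClassifier(criterion="gini", splitter="best",
                                     random_state=spec.seed, **hp)
    elif spec.kind == "RF":
        est = RandomForestClassifier(n_estimators=100, criterion="gini",
                                     random_state=spec.seed, **hp)
    else:  # NB
        est = GaussianNB(priors=None, var_smoothing=1e-9, **hp)
    if spec.kind in _STANDARDIZED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


class _Head:
    """Fitted head with a uniform predict / scores interface."""

    def __init__(self, spec: ClassifierSpec, estimator, classes: np.ndarray):
        self.spec = spec
        self.estimator = estimator
        self.classes_ = np.asarray(classes)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.scores(X), axis=1)]

    def scores(self, X) -> np.ndarray:
        """Per-class scores, rows summing to 1 for probabilistic kinds.

        The SVM head (probability calibration disabled, as in the printed
        defaults) reports its one-vs-rest decision values squashed through a
        logistic; these rank identically but are not a distribution.
        """
        X = np.asarray(X)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(X)
        d = self.estimator.decision_function(X)
        if d.ndim == 1:
            p = expit(d)
            return np.column_stack([1 - p, p])
        return expit(d)

    def score_positive(self, X, positive) -> np.ndarray:
        col = int(np.flatnonzero(self.classes_ == positive)[0])
        return self.scores(X)[:, col]


def _fit_head(spec: ClassifierSpec, X, y) -> _Head:
    est = clone(make_head(spec))
    est.fit(np.asarray(X), np.asarray(y))
    return _Head(spec, est, est.classes_ if hasattr(est, "classes_")
                 else est[-1].classes_)


def train_stage1(X, labels, spec: ClassifierSpec,
                 normal_label: str = NORMAL_LABEL) -> _Head:
    """Train the binary normal-vs-abnormal head on four-class labels.

    All non-normal labels are mapped to ``"ABNORMAL"``. The head exposes
    ``predict`` over {NORMAL, ABNORMAL} and ``score_positive(X, "ABNORMAL")``
    in [0, 1] for ROC analysis.
    """
    labels = np.asarray(labels)
    y = np.where(labels == normal_label, normal_label, "ABNORMAL")
    n_norm = int((y == normal_label).sum())
    if min(n_norm, len(y) - n_norm) < 2:
        raise ValueError("stage 1 needs >= 2 samples in each binary group")
    return _fit_head(spec, X, y)


def train_stage2(X, labels, spec: ClassifierSpec,
                 expected_classes: tuple[str, ...] = ABNORMAL_CLASSES) -> _Head:
    """Train the disease-subtype head on abnormal samples only."""
    labels = np.asarray(labels)
    present, counts = np.unique(labels, return_counts=True)
    absent = sorted(set(expected_classes) - set(present))
    if absent:
        raise ValueError(f"stage 2 training data is missing classes: {absent}")
    if counts.min() < 2:
        scarce = sorted(present[counts < 2])
        raise ValueError(f"stage 2 needs >= 2 samples per class; scarce: {scarce}")
    return _fit_head(spec, X, labels)


def train_all_at_once(X, labels, spec: ClassifierSpec) -> _Head:
    """Train the flat four-class head (same score contract as stage 2)."""
    labels = np.asarray(labels)
    present, counts = np.unique(labels, return_counts=True)
    if len(present) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        scarce = sorted(present[counts < 2])
        raise ValueError(f"need >= 2 samples per class; scarce: {scarce}")
    return _fit_head(spec, X, labels)


class CascadeClassifier(BaseEstimator, ClassifierMixin):
    """Normal-vs-abnormal gate followed by a disease-subtype head.

    scikit-learn classifier over fused feature rows; ``y`` holds the
    four-class string labels. Both stages use the same head kind by default.
    """

    def __init__(self, kind: str = "MLP", hyperparameters: dict | None = None,
                 threshold: float = 0.5, normal_label: str = NORMAL_LABEL,
                 random_state: int = 0):
        self.kind = kind
        self.hyperparameters = hyperparameters
        self.threshold = threshold
        self.normal_label = normal_label
        self.random_state = random_state

    def _spec(self) -> ClassifierSpec:
        return ClassifierSpec(self.kind, self.hyperparameters or {},
                              self.random_state)

    def fit(self, X, y) -> "CascadeClassifier":
        X, y = np.asarray(X), np.asarray(y)
        spec = self._spec()
        abnormal = sorted(set(y) - {self.normal_label})
        self.stage1_ = train_stage1(X, y, spec, self.normal_label)
        mask = y != self.normal_label
        self.stage2_ = train_stage2(X[mask], y[mask], spec,
                                    expected_classes=tuple(abnormal))
        self.classes_ = np.asarray(sorted(set(y)))
        return self

    def stage1_score(self, X) -> np.ndarray:
        """P(abnormal) per sample (logistic-squashed margin for SVM)."""
        return self.stage1_.score_positive(np.asarray(X), "ABNORMAL")

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        s1 = self.stage1_score(X)
        out = np.empty(len(X), dtype=object)
        gate = s1 >= self.threshold
        out[~gate] = self.normal_label
        if gate.any():
            sc = self.stage2_.scores(X[gate])
            # np.argmax takes the first maximum -> lowest class index on ties
            out[gate] = self.stage2_.classes_[np.argmax(sc, axis=1)]
        return out.astype(str)

    def predict_proba(self, X) -> np.ndarray:
        """Combined distribution: P(NORMAL)=1-s1, P(c)=s1*P(c|abnormal)."""
        X = np.asarray(X)
        s1 = self.stage1_score(X)
        s2 = self.stage2_.scores(X)
        proba = np.zeros((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            if c == self.normal_label:
                proba[:, j] = 1.0 - s1
            else:
                k = int(np.flatnonzero(self.stage2_.classes_ == c)[0])
                proba[:, j] = s1 * s2[:, k]
        return proba


def predict_cascade(model: CascadeClassifier, feature: np.ndarray):
    """Predict one fused feature vector (or a matrix) through the cascade."""
    arr = np.asarray(feature)
    if arr.ndim == 1:
        return model.predict(arr[None, :])[0]
    return model.predict(arr)
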