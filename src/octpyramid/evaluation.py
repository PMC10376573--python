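"""Diagnostic-performance evaluation: confusion matrices, Acc/Sen/Spc, ROC
AUC, stratified k-fold cross-validation and paired t-tests.

Metric definitions, from the binary confusion counts TP/TN/FP/FN:

    Acc = (TN + TP) / (TN + TP + FN + FP)
    Sen = TP / (TP + FN)
    Spc = TN / (TN + FP)

For multiclass problems Acc is trace/total and Sen/Spc are unweighted
(macro) means of the per-class one-vs-rest values. A metric whose
denominator is zero is reported as an explicit undefined marker (NaN) and
excluded from macro averages — never silently zero.

AUC is the area under the ROC curve, equal to the Mann-Whitney rank
statistic (midranks on ties); multiclass AUC is the unweighted one-vs-rest
mean. Cross-validation is stratified by class and fully determined by its
seed; all fitting happens inside each training fold (no test-fold sample
influences any fitted component).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats
from sklearn import metrics as _skm
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["ConfusionMatrix", "MetricsReport", "FoldPlan", "UNDEFINED",
           "is_undefined", "confusion_matrix", "binary_metrics",
           "multiclass_metrics", "roc_auc", "make_folds", "cross_validate",
           "paired_ttest", "evaluate_features", "format_report"]

UNDEFINED = float("nan")


def is_undefined(x) -> bool:
    """True for the undefined-metric marker (division by zero upstream)."""
    return bool(np.isnan(x))


@dataclasses.dataclass
class ConfusionMatrix:
    """Square count matrix indexed (true class, predicted class)."""

    counts: np.ndarray
    class_order: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(y_true, y_pred, class_order) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #{true=i, pred=j}``."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    class_order = list(class_order)
    known = set(class_order)
    for name, ys in (("y_true", y_true), ("y_pred", y_pred)):
        bad = sorted(set(ys.tolist()) - known)
        if bad:
            raise ValueError(f"{name} contains labels outside class_order: {bad}")
    if len(y_true) == 0:
        c = np.zeros((len(class_order), len(class_order)), dtype=int)
    else:
        c = _skm.confusion_matrix(y_true, y_pred, labels=class_order)
    return ConfusionMatrix(counts=np.asarray(c, dtype=int), class_order=class_order)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def binary_metrics(cm: ConfusionMatrix, positive_class) -> tuple[float, float, float]:
    """(Acc, Sen, Spc) of a 2x2 confusion matrix for the given positive class."""
    if cm.counts.shape != (2, 2):
        raise ValueError(f"binary_metrics needs a 2x2 matrix, got {cm.counts.shape}")
    if positive_class not in cm.class_order:
        raise ValueError(f"unknown positive class {positive_class!r}")
    p = cm.class_order.index(positive_class)
    n = 1 - p
    tp, fn = cm.counts[p, p], cm.counts[p, n]
    fp, tn = cm.counts[n, p], cm.counts[n, n]
    return (_ratio(tn + tp, tn + tp + fn + fp),
            _ratio(tp, tp + fn),
            _ratio(tn, tn + fp))


def multiclass_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(Acc, macro Sen, macro Spc) via one-vs-rest expansion.

    Per-class undefined values (empty class) are excluded from the macro
    means; if every class is undefined the macro itself is undefined.
    """
    c = cm.counts
    if c.shape[0] != c.shape[1] or c.shape[0] < 2:
        raise ValueError("need a square matrix with >= 2 classes")
    total = c.sum()
    acc = _ratio(np.trace(c), total)
    sens, spcs = [], []
    for i in range(c.shape[0]):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens.append(_ratio(tp, tp + fn))
        spcs.append(_ratio(tn, tn + fp))
    with np.errstate(invalid="ignore"):
        sen = float(np.nanmean(sens)) if not np.all(np.isnan(sens)) else UNDEFINED
        spc = float(np.nanmean(spcs)) if not np.all(np.isnan(spcs)) else UNDEFINED
    return acc, sen, spc


def roc_auc(scores, labels, positive=None) -> float:
    """ROC AUC (Mann-Whitney statistic, midranks on ties).

    Binary: ``scores`` is a vector and ``labels`` binary (``positive`` names
    the positive label when labels are not {0, 1}). Multiclass: ``scores``
    is (n, k) aligned with sorted unique labels and the unweighted
    one-vs-rest mean is returned. Raises when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ROC needs both classes present")
    if scores.ndim == 1:
        if positive is None:
            positive = classes[-1]
        y = (labels == positive).astype(int)
        return float(_skm.roc_auc_score(y, scores))
    if scores.shape[1] != len(classes):
        raise ValueError(
            f"score matrix has {scores.shape[1]} columns for {len(classes)} classes")
    aucs = [float(_skm.roc_auc_score((labels == c).astype(int), scores[:, j]))
            for j, c in enumerate(classes)]
    return float(np.mean(aucs))


@dataclasses.dataclass
class FoldPlan:
    """Assignment of each sample to one of folds 1..k."""

    assignments: np.ndarray
    k: int
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels, k: int = 5, seed: int = 0, stratified: bool = True
               ) -> FoldPlan:
    """Deterministic (seeded) k-fold plan, stratified by class by default."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"stratification impossible: smallest class has {counts.min()} "
                f"< k={k} samples")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.zeros(n, dtype=int)
    for f, (_, test) in enumerate(splitter.split(np.zeros(n), labels), start=1):
        assignments[test] = f
    return FoldPlan(assignments=assignments, k=k, seed=seed, stratified=stratified)


@dataclasses.dataclass
class FoldMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float


@dataclasses.dataclass
class MetricsReport:
    """Per-fold and aggregated cross-validation metrics."""

    per_fold: list[FoldMetrics]
    confusion: ConfusionMatrix            # summed over folds
    k: int
    seed: int

    def _agg(self, fn) -> dict[str, float]:
        import warnings
        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN folds
            for m in ("accuracy", "sensitivity", "specificity", "auc"):
                out[m] = float(fn([getattr(f, m) for f in self.per_fold]))
        return out

    @property
    def mean(self) -> dict[str, float]:
        return self._agg(np.nanmean)

    @property
    def std(self) -> dict[str, float]:
        return self._agg(np.nanstd)

    @property
    def accuracy(self) -> float:
        return self.mean["accuracy"]

    def to_dict(self) -> dict:
        return {
            "k": self.k, "seed": self.seed,
            "mean": self.mean, "std": self.std,
            "per_fold": [dataclasses.asdict(f) for f in self.per_fold],
            "confusion": {"class_order": self.confusion.class_order,
                          "counts": self.confusion.counts.tolist()},
        }


def _take(X, idx):
    if isinstance(X, np.ndarray):
        return X[idx]
    return [X[i] for i in idx]


def cross_validate(factory, X, y, plan: FoldPlan) -> MetricsReport:
    """Fit-and-score a pipeline factory under a fold plan.

    ``factory()`` must return a fresh object with ``fit(X, y)`` and
    ``predict(X)`` (optionally ``predict_proba`` for AUC). Every fitted
    component sees only its training fold.
    """
    y = np.asarray(y)
    if len(y) != len(plan.assignments):
        raise ValueError("fold plan does not cover the dataset")
    class_order = sorted(np.unique(y).tolist())
    per_fold = []
    total = np.zeros((len(class_order), len(class_order)), dtype=int)
    for f in range(1, plan.k + 1):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        model = factory()
        model.fit(_take(X, tr), y[tr])
        pred = np.asarray(model.predict(_take(X, te)))
        cm = confusion_matrix(y[te], pred, class_order)
        total += cm.counts
        if len(class_order) == 2:
            acc, sen, spc = binary_metrics(cm, class_order[-1])
        else:
            acc, sen, spc = multiclass_metrics(cm)
        auc = UNDEFINED
        if hasattr(model, "predict_proba"):
            proba = np.asarray(model.predict_proba(_take(X, te)))
            try:
                auc = roc_auc(proba[:, -1] if len(class_order) == 2 else proba,
                              y[te], positive=class_order[-1])
            except ValueError:
                pass  # a fold may lack a class in pathological plans
        per_fold.append(FoldMetrics(acc, sen, spc, auc))
    return MetricsReport(per_fold=per_fold,
                         confusion=ConfusionMatrix(total, class_order),
                         k=plan.k, seed=plan.seed)


def paired_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired Student's t-test on fold-wise metric differences.

    Returns ``(t, p)`` with n-1 degrees of freedom. Zero-variance
    differences (including a == b elementwise) are a degenerate case and
    return the undefined marker for both values.
    """
    a, b = np.asarray(metric_a, dtype=float), np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return UNDEFINED, UNDEFINED
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# -- feature-table evaluation (CLI backend) ----------------------------------

def evaluate_features(X, y, classifiers=("MLP", "LR", "SVM", "DT", "RF", "NB"),
                      stages=("binary", "three", "four"), k: int = 5,
                      seed: int = 0, normal_label: str = "NORMAL") -> dict:
    """Cross-validate classifier heads over a fused-feature table.

    Stages: ``binary`` (normal vs. abnormal), ``three`` (disease subtypes,
    abnormal samples only), ``four`` (all-at-once), ``cascade`` (two-stage
    four-class). Returns a JSON-ready nested report.
    """
    from .cascade import CascadeClassifier, ClassifierSpec, make_head

    X, y = np.asarray(X), np.asarray(y)
    report: dict = {"k": k, "seed": seed, "stages": {}}
    for stage in stages:
        if stage == "binary":
            Xs, ys = X, np.where(y == normal_label, normal_label, "ABNORMAL")
        elif stage == "three":
            mask = y != normal_label
            Xs, ys = X[mask], y[mask]
        elif stage in ("four", "cascade"):
            Xs, ys = X, y
        else:
            raise ValueError(f"unknown stage '{stage}'")
        plan = make_folds(ys, k=k, seed=seed, stratified=True)
        stage_report = {}
        for kind in classifiers:
            spec = ClassifierSpec(kind, seed=seed)
            if stage == "cascade":
                factory = lambda s=spec: CascadeClassifier(
                    s.kind, normal_label=normal_label, random_state=s.seed)
            else:
                factory = lambda s=spec: make_head(s)
            stage_report[spec.kind] = cross_validate(factory, Xs, ys, plan).to_dict()
        report["stages"][stage] = stage_report
    return report


def format_report(report: dict) -> str:
    """Human-readable table (per stage, Acc/Sen/Spc/AUC in %) of a report."""
    lines = []
    for stage, per_clf in report["stages"].items():
        lines.append(f"[{stage}]  (k={report['k']}, seed={report['seed']})")
        lines.append(f"{'clf':<6}{'Acc%':>8}{'Sen%':>8}{'Spc%':>8}{'AUC%':>8}")
        for kind, rep in per_clf.items():
            m = rep["mean"]
            row = [kind] + [
                f"{100 * m[x]:.2f}" if np.isfinite(m[x]) else "--"
                for x in ("accuracy", "sensitivity", "specificity", "auc")]
            lines.append(f"{row[0]:<6}{row[1]:>8}{row[2]:>8}{row[3]:>8}{row[4]:>8}")
        lines.append("")
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
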