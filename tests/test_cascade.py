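"""Cascade classifier: head construction, gating soundness, score
contracts, tie-breaks and null calibration."""

import numpy as np
import pytest
from scipy import stats

from octpyramid.cascade import (ABNORMAL_CLASSES, CascadeClassifier,
                                ClassifierSpec, _Head, make_head,
                                predict_cascade, train_all_at_once,
                                train_stage1, train_stage2)


def test_unknown_kind_rejected():
    with pytest.raises(ValueError, match="unknown classifier kind"):
        ClassifierSpec("KNN")


def test_kind_is_case_insensitive():
    assert ClassifierSpec("svm").kind == "SVM"


class TestSeparableFixture:
    def test_stage1_mlp_reaches_perfect_training_accuracy(self, blob_features):
        X, y = blob_features
        head = train_stage1(X, y, ClassifierSpec("MLP"))
        pred = head.predict(X)
        expected = np.where(y == "NORMAL", "NORMAL", "ABNORMAL")
        assert (pred == expected).mean() == 1.0

    def test_stage2_perfect_on_separable_blobs(self, blob_features):
        X, y = blob_features
        mask = y != "NORMAL"
        head = train_stage2(X[mask], y[mask], ClassifierSpec("LR"))
        assert (head.predict(X[mask]) == y[mask]).mean() == 1.0

    def test_all_at_once_perfect_and_agrees_with_cascade(self, blob_features):
        X, y = blob_features
        flat = train_all_at_once(X, y, ClassifierSpec("LR"))
        cascade = CascadeClassifier("LR").fit(X, y)
        assert (flat.predict(X) == y).mean() == 1.0
        assert np.array_equal(cascade.predict(X), flat.predict(X))

    def test_dt_predicts_training_label_for_duplicates(self, blob_features):
        X, y = blob_features
        mask = y != "NORMAL"
        head = train_stage2(X[mask], y[mask], ClassifierSpec("DT"))
        assert np.array_equal(head.predict(X[mask][:5]), y[mask][:5])


@pytest.mark.parametrize("kind", ["MLP", "LR", "RF", "NB"])
def test_probabilistic_scores_are_distributions(kind, blob_features):
    X, y = blob_features
    mask = y != "NORMAL"
    head = train_stage2(X[mask], y[mask], ClassifierSpec(kind))
    s = head.scores(X[mask])
    assert np.all(s >= 0)
    assert np.allclose(s.sum(axis=1), 1.0, atol=1e-6)


def test_svm_scores_rank_but_are_not_a_distribution(blob_features):
    X, y = blob_features
    head = train_stage1(X, y, ClassifierSpec("SVM"))
    s = head.score_positive(X, "ABNORMAL")
    assert np.all((0 <= s) & (s <= 1))


class TestGating:
    def test_normal_only_from_stage1_negatives(self, blob_features):
        X, y = blob_features
        model = CascadeClassifier("LR").fit(X, y)
        pred = model.predict(X)
        s1 = model.stage1_score(X)
        assert np.array_equal(pred == "NORMAL", s1 < model.threshold)
        assert set(pred[s1 >= model.threshold]) <= set(ABNORMAL_CLASSES)

    def test_extreme_threshold_gates_everything_normal(self, blob_features):
        X, y = blob_features
        model = CascadeClassifier("LR", threshold=1.1).fit(X, y)
        assert set(model.predict(X)) == {"NORMAL"}

    def test_tie_breaks_to_lowest_class_index(self):
        class _Stub:
            classes_ = np.array(["CNV", "DME", "DRUSEN"])

            def predict_proba(self, X):
                return np.tile([0.4, 0.4, 0.2], (len(X), 1))

        head = _Head(ClassifierSpec("LR"), _Stub(), _Stub.classes_)
        assert head.predict(np.zeros((3, 2))).tolist() == ["CNV"] * 3

    def test_argmax_picks_highest_score(self, blob_features):
        class _Stub:
            classes_ = np.array(["CNV", "DME", "DRUSEN"])

            def predict_proba(self, X):
                return np.tile([0.2, 0.7, 0.1], (len(X), 1))

        head = _Head(ClassifierSpec("LR"), _Stub(), _Stub.classes_)
        assert head.predict(np.zeros((1, 2)))[0] == "DME"

    def test_predict_cascade_single_vector(self, blob_features):
        X, y = blob_features
        model = CascadeClassifier("LR").fit(X, y)
        assert predict_cascade(model, X[0]) == model.predict(X[:1])[0]

    def test_predict_proba_is_a_distribution(self, blob_features):
        X, y = blob_features
        model = CascadeClassifier("LR").fit(X, y)
        p = model.predict_proba(X)
        assert p.shape == (len(X), 4)
        assert np.all(p >= 0)


class TestErrors:
    def test_stage1_single_group(self, blob_features):
        X, y = blob_features
        with pytest.raises(ValueError, match="binary group"):
            train_stage1(X[y != "NORMAL"], y[y != "NORMAL"], ClassifierSpec("LR"))

    def test_stage2_missing_class_listed(self, blob_features):
        X, y = blob_features
        mask = np.isin(y, ["CNV", "DME"])
        with pytest.raises(ValueError, match=r"\['DRUSEN'\]"):
            train_stage2(X[mask], y[mask], ClassifierSpec("LR"))

    def test_feature_length_mismatch(self, blob_features):
        X, y = blob_features
        model = CascadeClassifier("LR").fit(X, y)
        with pytest.raises(ValueError):
            model.predict(X[:, :3])


@pytest.fixture(scope="module")
def noise():
    rng = np.random.default_rng(123)
    X = rng.normal(size=(200, 10))
    y = np.repeat(["NORMAL", "CNV", "DME", "DRUSEN"], 50)
    return X, y


class TestNullCalibration:
    """On pure-noise features the system must not hallucinate signal."""

    def test_stage1_accuracy_within_binomial_band_of_majority(self, noise):
        from octpyramid.evaluation import make_folds
        X, y = noise
        yb = np.where(y == "NORMAL", "NORMAL", "ABNORMAL")
        plan = make_folds(yb, k=5, seed=0)
        correct = 0
        for f in range(1, 6):
            tr, te = plan.train_indices(f), plan.test_indices(f)
            head = train_stage1(X[tr], y[tr], ClassifierSpec("LR"))
            correct += int((head.predict(X[te]) == yb[te]).sum())
        acc = correct / len(y)
        p0 = 0.75  # majority (abnormal) rate
        half = stats.norm.ppf(0.995) * np.sqrt(p0 * (1 - p0) / len(y))
        assert p0 - half <= acc <= p0 + half

    def test_four_class_on_noise_is_at_chance(self, noise):
        from octpyramid.evaluation import make_folds
        X, y = noise
        plan = make_folds(y, k=5, seed=0)
        correct = 0
        for f in range(1, 6):
            tr, te = plan.train_indices(f), plan.test_indices(f)
            head = train_all_at_once(X[tr], y[tr], ClassifierSpec("LR"))
            correct += int((head.predict(X[te]) == y[te]).sum())
        acc = correct / len(y)
        sigma = np.sqrt(0.25 * 0.75 / len(y))
        assert abs(acc - 0.25) <= 3 * sigma
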