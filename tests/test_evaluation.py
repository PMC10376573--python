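"""Evaluation machinery against independent oracles: confusion counting,
Acc/Sen/Spc formulas, rank-statistic AUC, fold plans, leakage and t-tests."""

import numpy as np
import pytest

from octpyramid.evaluation import (ConfusionMatrix, binary_metrics,
                                   confusion_matrix, cross_validate,
                                   evaluate_features, format_report,
                                   is_undefined, make_folds,
                                   multiclass_metrics, paired_ttest, roc_auc)


class TestConfusionMatrix:
    def test_hand_count(self):
        cm = confusion_matrix(["N", "N", "A", "A"], ["N", "A", "A", "A"],
                              ["N", "A"])
        assert cm.counts.tolist() == [[1, 1], [0, 2]]

    def test_perfect_predictions_are_diagonal(self):
        y = ["a", "b", "c", "a"]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_empty_inputs_give_zero_matrix(self):
        cm = confusion_matrix([], [], ["a", "b"])
        assert cm.counts.sum() == 0 and cm.counts.shape == (2, 2)

    def test_unknown_label_is_named(self):
        with pytest.raises(ValueError, match="X"):
            confusion_matrix(["a", "X"], ["a", "a"], ["a", "b"])


class TestBinaryMetrics:
    def test_perfect(self):
        cm = ConfusionMatrix(np.array([[1, 0], [0, 1]]), ["neg", "pos"])
        assert binary_metrics(cm, "pos") == (1.0, 1.0, 1.0)

    def test_formula_example(self):
        # TP=95, FN=5, TN=90, FP=10
        cm = ConfusionMatrix(np.array([[95, 5], [10, 90]]), ["pos", "neg"])
        acc, sen, spc = binary_metrics(cm, "pos")
        assert (acc, sen, spc) == (0.925, 0.95, 0.90)

    def test_zero_denominator_yields_undefined_marker(self):
        cm = ConfusionMatrix(np.array([[0, 0], [10, 90]]), ["pos", "neg"])
        _, sen, _ = binary_metrics(cm, "pos")
        assert is_undefined(sen)

    def test_formula_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fn, fp, tn = rng.integers(0, 50, size=4)
            cm = ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), ["p", "n"])
            acc, sen, spc = binary_metrics(cm, "p")
            tot = tp + fn + fp + tn
            if tot:
                assert acc == (tn + tp) / tot
            if tp + fn:
                assert sen == tp / (tp + fn)
            if tn + fp:
                assert spc == tn / (tn + fp)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(ConfusionMatrix(np.zeros((3, 3), int),
                                           ["a", "b", "c"]), "a")


def _ovr_oracle(counts):
    """Brute-force one-vs-rest expansion of a multiclass matrix."""
    counts = np.asarray(counts)
    sens, spcs = [], []
    for i in range(counts.shape[0]):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = counts.sum() - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spcs.append(tn / (tn + fp) if tn + fp else np.nan)
    return np.nanmean(sens), np.nanmean(spcs)


class TestMulticlassMetrics:
    def test_identity_confusion(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5]), ["a", "b", "c"])
        assert multiclass_metrics(cm) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        counts = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]])
        acc, sen, spc = multiclass_metrics(ConfusionMatrix(counts, list("abc")))
        assert acc == pytest.approx(0.8)
        o_sen, o_spc = _ovr_oracle(counts)
        assert sen == pytest.approx(o_sen) == pytest.approx(0.8)
        assert spc == pytest.approx(o_spc) == pytest.approx(0.9)

    def test_random_matrices_match_ovr_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            c = rng.integers(0, 20, size=(4, 4))
            acc, sen, spc = multiclass_metrics(ConfusionMatrix(c, list("abcd")))
            o_sen, o_spc = _ovr_oracle(c)
            if c.sum():
                assert acc == np.trace(c) / c.sum()
            np.testing.assert_allclose([sen, spc], [o_sen, o_spc])

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(2)
        n, C = 4000, 4
        y = rng.integers(0, C, n)
        p = rng.integers(0, C, n)
        cm = confusion_matrix(y.tolist(), p.tolist(), list(range(C)))
        acc, _, _ = multiclass_metrics(cm)
        assert abs(acc - 1 / C) <= 3 * np.sqrt((1 / C) * (1 - 1 / C) / n)


def _auc_bruteforce(scores, labels):
    """Pairwise comparison of every positive-negative pair, ties = 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pairwise_bruteforce_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 51))
            labels = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert roc_auc(scores, labels) == pytest.approx(
                _auc_bruteforce(scores, labels))

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(10)
        n = 4000
        labels = rng.integers(0, 2, n)
        auc = roc_auc(rng.random(n), labels)
        n_pos = labels.sum()
        n_neg = n - n_pos
        # exact null standard deviation of the Mann-Whitney AUC
        sd = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(auc - 0.5) < 3 * sd

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_multiclass_is_macro_ovr_mean(self):
        rng = np.random.default_rng(5)
        y = np.repeat(["a", "b", "c"], 20)
        s = rng.random((60, 3))
        expected = np.mean([roc_auc(s[:, j], (y == c).astype(int), positive=1)
                            for j, c in enumerate(["a", "b", "c"])])
        assert roc_auc(s, y) == pytest.approx(expected)


class TestFoldPlans:
    def test_even_split(self):
        plan = make_folds(np.repeat(["a", "b"], 50), k=5, seed=0)
        sizes = [len(plan.test_indices(f)) for f in range(1, 6)]
        assert sizes == [20] * 5

    def test_stratification_balance(self):
        y = np.array(["a"] * 40 + ["b"] * 40 + ["c"] * 10 + ["d"] * 10)
        plan = make_folds(y, k=5, seed=1)
        for f in range(1, 6):
            te = y[plan.test_indices(f)]
            assert [list(te).count(c) for c in "abcd"] == [8, 8, 2, 2]

    def test_cover_and_disjoint(self):
        plan = make_folds(np.repeat(["a", "b"], 20), k=4, seed=2)
        assert sorted(np.unique(plan.assignments)) == [1, 2, 3, 4]
        assert len(plan.assignments) == 40  # each sample in exactly one fold

    def test_seed_determinism(self):
        y = np.repeat(["a", "b"], 25)
        p1, p2 = make_folds(y, seed=9), make_folds(y, seed=9)
        assert np.array_equal(p1.assignments, p2.assignments)

    def test_small_class_rejected_when_stratified(self):
        with pytest.raises(ValueError, match="stratification"):
            make_folds(["a"] * 20 + ["b"] * 3, k=5)

    def test_fewer_samples_than_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5)


class _Memorizer:
    """Predicts the stored label for exact feature matches, else class 0.

    Train accuracy is 1.0 by construction; on unseen unique features its
    held-out accuracy must collapse to the majority-guess level. A leakage
    bug anywhere in cross_validate would show up as inflated test accuracy.
    """

    def fit(self, X, y):
        self.table = {tuple(row): label for row, label in zip(np.asarray(X), y)}
        self.default = y[0]
        return self

    def predict(self, X):
        return np.array([self.table.get(tuple(row), self.default)
                         for row in np.asarray(X)])


@pytest.fixture(scope="module")
def unique_noise():
    rng = np.random.default_rng(6)
    return rng.random((100, 8)), np.repeat(["a", "b"], 50)


class TestCrossValidate:

    def test_leakage_canary(self, unique_noise):
        X, y = unique_noise
        plan = make_folds(y, k=5, seed=0)
        report = cross_validate(_Memorizer, X, y, plan)
        # memorizer always falls back to its first training label
        assert report.accuracy <= 0.6
        model = _Memorizer().fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_fold_count_and_mean_consistency(self, unique_noise):
        X, y = unique_noise
        plan = make_folds(y, k=5, seed=0)
        report = cross_validate(_Memorizer, X, y, plan)
        assert len(report.per_fold) == 5
        accs = [f.accuracy for f in report.per_fold]
        assert report.mean["accuracy"] == pytest.approx(np.mean(accs), abs=1e-12)

    def test_plan_dataset_mismatch(self, unique_noise):
        X, y = unique_noise
        plan = make_folds(y, k=5, seed=0)
        with pytest.raises(ValueError):
            cross_validate(_Memorizer, X[:50], y[:50], plan)


class TestPairedTTest:
    def test_identical_vectors_are_degenerate(self):
        t, p = paired_ttest([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert is_undefined(t) and is_undefined(p)

    def test_constant_difference_is_degenerate(self):
        t, p = paired_ttest([2, 2, 2, 2, 2], [1, 1, 1, 1, 1])
        assert is_undefined(t)

    def test_matches_closed_form(self):
        a = np.array([0.9, 0.92, 0.88, 0.91, 0.9])
        b = np.array([0.85, 0.86, 0.84, 0.88, 0.83])
        t, p = paired_ttest(a, b)
        d = a - b
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist
        p_expected = 2 * tdist.sf(abs(t_expected), len(d) - 1)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_ttest([1, 2, 3], [1, 2])


def test_evaluate_features_report_structure(blob_features):
    X, y = blob_features
    report = evaluate_features(X, y, classifiers=("LR", "NB"),
                               stages=("binary", "three", "four", "cascade"),
                               k=3, seed=0)
    assert set(report["stages"]) == {"binary", "three", "four", "cascade"}
    for stage, per_clf in report["stages"].items():
        for kind in ("LR", "NB"):
            acc = per_clf[kind]["mean"]["accuracy"]
            assert 0.0 <= acc <= 1.0
    # separable blobs: the linear model should be essentially perfect
    assert report["stages"]["four"]["LR"]["mean"]["accuracy"] > 0.9
    text = format_report(report)
    assert "binary" in text and "LR" in text
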