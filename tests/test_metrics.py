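"""Tests for the evaluation metrics and the CV / hold-out harnesses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpsubtype import (
    binary_metrics,
    compute_report,
    confusion_matrix,
    cross_validate,
    default_scheme,
    group_metrics,
    holdout_split,
    multiclass_metrics,
    stratified_fold_indices,
)
from rpsubtype.metrics import per_class_counts


def direct_binary(TP, FP, TN, FN):
    """Independent evaluation of the accuracy / F1 / MCC definitions."""
    n = TP + FP + TN + FN
    acc = (TP + TN) / n
    f1 = 2 * TP / (2 * TP + FP + FN) if 2 * TP + FP + FN else 0.0
    rad = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(rad) if rad else 0.0
    return acc, f1, mcc


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        y = ["a", "b", "b", "c"]
        C = confusion_matrix(y, y, ["a", "b", "c"])
        np.testing.assert_array_equal(C, np.diag([1, 2, 1]))

    def test_single_off_diagonal(self):
        C = confusion_matrix(["A"], ["B"], ["A", "B"])
        np.testing.assert_array_equal(C, [[0, 1], [0, 0]])

    def test_unknown_label_errors(self):
        with pytest.raises(ValueError, match="not in class_order"):
            confusion_matrix(["A"], ["Z"], ["A", "B"])

    @given(st.lists(st.tuples(st.sampled_from("abc"), st.sampled_from("abc")), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_row_sums_are_true_class_counts(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        C = confusion_matrix(y_true, y_pred, ["a", "b", "c"])
        assert C.sum() == len(pairs)
        for i, c in enumerate("abc"):
            assert C[i].sum() == y_true.count(c)


class TestBinaryMetrics:
    def test_hand_example(self):
        m = binary_metrics(TP=50, FP=5, TN=40, FN=5)
        assert m.accuracy == pytest.approx(0.9)
        assert m.f1 == pytest.approx(100 / 110)
        assert m.mcc == pytest.approx(1975 / 2475)

    def test_perfect_classifier(self):
        m = binary_metrics(TP=7, FP=0, TN=3, FN=0)
        assert (m.accuracy, m.f1, m.mcc) == (1.0, 1.0, 1.0)

    def test_all_wrong_limit(self):
        m = binary_metrics(TP=0, FP=4, TN=0, FN=6)
        assert m.accuracy == 0.0 and m.f1 == 0.0 and m.mcc == pytest.approx(-1.0)

    def test_zero_denominator_convention(self):
        # no predicted positives and no true positives -> MCC factor 0 -> 0
        m = binary_metrics(TP=0, FP=0, TN=5, FN=0)
        assert m.mcc == 0.0 and m.f1 == 0.0 and m.accuracy == 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            binary_metrics(0, 0, 0, 0)

    @given(st.tuples(*[st.integers(0, 20)] * 4))
    @settings(deadline=None, max_examples=200)
    def test_matches_direct_formula(self, counts):
        TP, FP, TN, FN = counts
        if TP + FP + TN + FN == 0:
            return
        m = binary_metrics(TP, FP, TN, FN)
        acc, f1, mcc = direct_binary(TP, FP, TN, FN)
        assert m.accuracy == pytest.approx(acc, abs=1e-12)
        assert m.f1 == pytest.approx(f1, abs=1e-12)
        assert m.mcc == pytest.approx(mcc, abs=1e-12)

    def test_f1_invariant_to_tn(self):
        a = binary_metrics(TP=8, FP=3, TN=1, FN=2)
        b = binary_metrics(TP=8, FP=3, TN=500, FN=2)
        assert a.f1 == b.f1

    def test_mcc_sign_flips_on_inverted_predictions(self):
        a = binary_metrics(TP=8, FP=3, TN=6, FN=2)
        flipped = binary_metrics(TP=2, FP=6, TN=3, FN=8)  # swap pred pos/neg
        assert flipped.mcc == pytest.approx(-a.mcc)


def brute_force_aggregates(C):
    """Per-definition oracle for the multiclass aggregations."""
    C = np.asarray(C, dtype=float)
    n = C.sum()
    acc = np.trace(C) / n
    f1s, mccs, sup = [], [], []
    for i in range(C.shape[0]):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        tn = n - tp - fn - fp
        _, f1, mcc = direct_binary(tp, fp, tn, fn)
        f1s.append(f1)
        mccs.append(mcc)
        sup.append(tp + fn)
    f1s, mccs, sup = np.array(f1s), np.array(mccs), np.array(sup)
    ok = sup > 0
    f1w = float(np.sum(f1s[ok] * sup[ok]) / sup[ok].sum())
    f1m = float(f1s[ok].mean())
    mcc_ovr = float(mccs[ok].mean())
    # Gorodkin from the raw definition via per-sample indicator covariances
    t, p = C.sum(axis=1), C.sum(axis=0)
    num = np.trace(C) * n - t @ p
    den = math.sqrt(n * n - p @ p) * math.sqrt(n * n - t @ t)
    return acc, f1w, f1m, (num / den if den else 0.0), mcc_ovr


class TestMulticlassMetrics:
    def test_diagonal_confusion_all_ones(self):
        agg = multiclass_metrics(np.diag([5, 3, 9]))
        assert agg.accuracy == agg.f1_weighted == agg.f1_macro == agg.mcc == 1.0

    def test_two_class_gorodkin_reduces_to_binary(self):
        C = np.array([[8, 2], [3, 7]])
        agg = multiclass_metrics(C)
        binary = binary_metrics(TP=8, FP=3, TN=7, FN=2)
        assert agg.mcc == pytest.approx(binary.mcc, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            C = rng.integers(0, 30, size=(4, 4))
            if C.sum() == 0:
                continue
            agg = multiclass_metrics(C)
            acc, f1w, f1m, mcc, mcc_ovr = brute_force_aggregates(C)
            assert agg.accuracy == pytest.approx(acc, abs=1e-12)
            assert agg.f1_weighted == pytest.approx(f1w, abs=1e-12)
            assert agg.f1_macro == pytest.approx(f1m, abs=1e-12)
            assert agg.mcc == pytest.approx(mcc, abs=1e-12)
            assert agg.mcc_ovr_mean == pytest.approx(mcc_ovr, abs=1e-12)

    def test_matches_sklearn(self):
        # independent library route for the same aggregations
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

        rng = np.random.default_rng(1)
        y_true = rng.choice(list("abcd"), size=200)
        y_pred = np.where(rng.random(200) < 0.7, y_true, rng.choice(list("abcd"), size=200))
        C = confusion_matrix(y_true, y_pred, list("abcd"))
        agg = multiclass_metrics(C)
        assert agg.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert agg.f1_weighted == pytest.approx(f1_score(y_true, y_pred, average="weighted"))
        assert agg.f1_macro == pytest.approx(f1_score(y_true, y_pred, average="macro"))
        assert agg.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_accuracy_equals_mean_correctness(self):
        rng = np.random.default_rng(2)
        y_true = rng.choice(list("ab"), size=50)
        y_pred = rng.choice(list("ab"), size=50)
        C = confusion_matrix(y_true, y_pred, ["a", "b"])
        assert multiclass_metrics(C).accuracy == pytest.approx(np.mean(y_true == y_pred))

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            multiclass_metrics(np.zeros((3, 3)))

    def test_per_class_counts_sum_to_n(self):
        C = np.array([[5, 1, 0], [2, 6, 1], [0, 0, 4]])
        for pc in per_class_counts(C):
            assert pc["TP"] + pc["FP"] + pc["TN"] + pc["FN"] == C.sum()


class TestGroupMetrics:
    scheme = default_scheme()

    def test_all_correct_gives_ones(self):
        classes = list(self.scheme.labels)
        C = np.diag(np.arange(2, 22))
        out = group_metrics(C, classes, self.scheme)
        assert set(out) == set(self.scheme.groups)
        for m in out.values():
            assert m.accuracy == pytest.approx(1.0)
            assert m.f1_weighted == pytest.approx(1.0)
            assert m.mcc == pytest.approx(1.0)

    def test_group_membership_routes_errors(self):
        # Ph-like (Fusion Gene) predicted as PAX5alt (TF Alteration) hurts
        # only the Fusion Gene rollup
        classes = list(self.scheme.labels)
        C = np.diag([5] * 20)
        i = classes.index("Ph-like")
        j = classes.index("PAX5alt")
        C[i, j] += 5
        out = group_metrics(C, classes, self.scheme)
        assert out["Fusion Gene"].accuracy < 1.0
        assert out["TF Alteration"].accuracy == 1.0
        assert out["Ploidy"].accuracy == 1.0

    def test_class_without_group_errors(self):
        with pytest.raises(ValueError, match="without a group"):
            group_metrics(np.eye(2, dtype=int), ["Ph", "mystery"], self.scheme)

    def test_report_includes_groups(self):
        y = ["Ph-like", "PAX5alt", "HLF", "iAMP21", "Ph-like"]
        rep = compute_report(y, y, sorted(set(y)), self.scheme)
        assert rep.group["Rare Subtype"].accuracy == 1.0
        assert rep.per_class["Ph-like"]["recall"] == 1.0


class TestHoldoutSplit:
    def test_thirty_percent_of_hundred(self):
        y = np.repeat(["a", "b"], 50)
        train, test = holdout_split(y, 0.3, seed=0)
        assert len(test) == 30 and len(train) == 70
        assert len(np.intersect1d(train, test)) == 0

    def test_small_class_keeps_train_member(self):
        y = np.array(["a"] * 97 + ["b"] * 3)
        train, test = holdout_split(y, 0.3, seed=1)
        assert (y[train] == "b").sum() >= 1

    def test_reproducible(self):
        y = np.repeat(list("abc"), 20)
        a = holdout_split(y, 0.3, seed=9)
        b = holdout_split(y, 0.3, seed=9)
        np.testing.assert_array_equal(a[1], b[1])

    def test_stratified_proportions(self):
        y = np.repeat(["a", "b", "c"], [60, 30, 10])
        _, test = holdout_split(y, 0.3, seed=2)
        counts = {c: (y[test] == c).sum() for c in "abc"}
        assert counts == {"a": 18, "b": 9, "c": 3}

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            holdout_split(np.array(["a", "b"]), 1.5)


class TestStratifiedFolds:
    def test_partition(self):
        y = np.repeat(list("abc"), [25, 15, 10])
        folds = stratified_fold_indices(y, k=5, seed=0)
        allidx = np.concatenate(folds)
        assert len(allidx) == 50 and len(np.unique(allidx)) == 50

    def test_class_proportions_within_one(self):
        y = np.repeat(list("abc"), [25, 15, 11])
        folds = stratified_fold_indices(y, k=5, seed=3)
        for c, n_c in zip("abc", (25, 15, 11)):
            per_fold = [np.sum(y[f] == c) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1

    def test_small_class_warns(self):
        y = np.array(["a"] * 20 + ["b"] * 3)
        with pytest.warns(UserWarning, match="fewer than 5"):
            stratified_fold_indices(y, k=5, seed=0)

    def test_k_below_two_errors(self):
        with pytest.raises(ValueError):
            stratified_fold_indices(np.array(["a", "b"]), k=1)


class TestCrossValidate:
    def test_separable_data_high_accuracy(self, small_log2, small_data):
        cv = cross_validate(small_log2, small_data.labels, k=5, d=50, M=3, seed=1)
        assert cv.accuracy >= 0.95

    def test_same_seed_reproduces_metrics(self, small_log2, small_data):
        a = cross_validate(small_log2, small_data.labels, k=5, d=30, M=2, seed=4)
        b = cross_validate(small_log2, small_data.labels, k=5, d=30, M=2, seed=4)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.accuracy == b.accuracy

    def test_member_accuracies_available(self, small_log2, small_data):
        cv = cross_validate(
            small_log2, small_data.labels, k=5, d=30, M=3, seed=4, collect_members=True
        )
        accs = cv.member_accuracies()
        assert accs.shape == (3,)
        assert np.all((0 <= accs) & (accs <= 1))
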