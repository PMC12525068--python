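"""Evaluation metrics against hand-worked values and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from laryvid.metrics import (
    ConfusionMatrix,
    confusion_matrix,
    cross_validate,
    mcc,
    metric_report,
    per_class_prf,
    roc_auc_ovr,
    roc_curve_points,
)


def _cm(counts):
    counts = np.asarray(counts)
    return ConfusionMatrix(counts, tuple(f"c{i}" for i in range(len(counts))))


def _binary_cm(tp, fp, fn, tn):
    # rows = true (pos first), cols = predicted
    return _cm([[tp, fn], [fp, tn]])


def mcc_binary_closed_form(tp, fp, fn, tn):
    den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return (tp * tn - fp * fn) / den if den else 0.0


def auc_pair_counting(y_true, scores, positive):
    """Oracle: exhaustive positive-negative pair comparison with half
    credit for ties."""
    pos = [s for s, y in zip(scores, y_true) if y == positive]
    neg = [s for s, y in zip(scores, y_true) if y != positive]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = [0, 1, 2, 1, 0]
        cm = confusion_matrix(y, y, 3)
        assert np.array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_fully_wrong_zero_diagonal(self):
        cm = confusion_matrix([0, 1, 2], [1, 2, 0], 3)
        assert np.trace(cm.counts) == 0

    def test_matches_direct_counting_oracle(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion_matrix(y_true, y_pred, 4)
        expected = np.zeros((4, 4), dtype=int)
        for t, p in zip(y_true, y_pred):
            expected[t, p] += 1
        assert np.array_equal(cm.counts, expected)
        assert np.array_equal(cm.counts.sum(axis=1), np.bincount(y_true, minlength=4))

    def test_one_vs_rest_consistency(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        cm = confusion_matrix(y_true, y_pred, 3)
        for c in range(3):
            tp, fp, fn, tn = cm.one_vs_rest(c)
            assert tp + fn == cm.counts[c].sum()
            assert tp + fp == cm.counts[:, c].sum()
            assert tp + fp + fn + tn == cm.total

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix([0, 1], [0], 2)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], 3)


class TestPerClassPRF:
    def test_hand_worked_binary_case(self):
        # TP=8, FP=2, FN=8: P=0.8, R=0.5, F1=2*0.4/1.3
        cm = _binary_cm(tp=8, fp=2, fn=8, tn=10)
        row = per_class_prf(cm).iloc[0]
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(0.5)
        assert row["f1"] == pytest.approx(2 * 0.4 / 1.3)  # 0.6153846...

    def test_perfect_diagonal_all_ones(self):
        prf = per_class_prf(_cm(np.diag([5, 7, 9])))
        assert (prf[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_never_predicted_class_is_zero_with_warning(self):
        cm = _cm([[0, 3], [0, 5]])  # column 0 all zero
        with pytest.warns(UserWarning, match="precision"):
            prf = per_class_prf(cm)
        assert prf.iloc[0]["precision"] == 0.0

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        y_true = rng.integers(0, 3, 120)
        y_pred = rng.integers(0, 3, 120)
        prf = per_class_prf(confusion_matrix(y_true, y_pred, 3))
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2], zero_division=0
        )
        assert np.allclose(prf["precision"], p)
        assert np.allclose(prf["recall"], r)
        assert np.allclose(prf["f1"], f)


class TestMCC:
    def test_hand_worked_binary_value(self):
        # (50*40 - 5*5) / sqrt(55*55*45*45) = 1975/2475
        cm = _binary_cm(tp=50, fp=5, fn=5, tn=40)
        assert mcc(cm) == pytest.approx(1975 / 2475)
        assert mcc(cm) == pytest.approx(0.7980, abs=5e-5)

    def test_perfect_diagonal_is_one(self):
        assert mcc(_cm(np.diag([4, 9, 2]))) == pytest.approx(1.0)

    def test_independent_predictions_are_zero(self):
        # outer-product matrix: prediction independent of truth
        t = np.array([10, 20, 30])
        p = np.array([0.5, 0.3, 0.2])
        cm = _cm(np.outer(t, p) * 1.0)
        assert mcc(cm) == pytest.approx(0.0, abs=1e-12)

    def test_multiclass_reduces_to_binary_closed_form(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 20, 4)
            cm = _binary_cm(tp, fp, fn, tn)
            assert mcc(cm) == pytest.approx(
                mcc_binary_closed_form(tp, fp, fn, tn), abs=1e-12
            )

    def test_agrees_with_sklearn_on_random_3class(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(20):
            y_true = rng.integers(0, 3, 80)
            y_pred = rng.integers(0, 3, 80)
            cm = confusion_matrix(y_true, y_pred, 3)
            assert mcc(cm) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )

    def test_degenerate_matrix_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="MCC"):
            assert mcc(_cm([[5, 0], [0, 0]])) == 0.0


class TestROCAUC:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert np.allclose(roc_auc_ovr(y, probs), [1.0, 1.0])

    def test_tie_case_matches_pair_counting_oracle(self):
        y = [0, 0, 0, 1, 1, 1]
        s1 = [0.8, 0.5, 0.3, 0.5, 0.2, 0.1]  # one tie at 0.5
        probs = np.column_stack([s1, 1 - np.asarray(s1)])
        aucs = roc_auc_ovr(y, probs)
        assert aucs[0] == pytest.approx(auc_pair_counting(y, s1, 0))

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 3000)
        s = rng.random(3000)
        probs = np.column_stack([s, 1 - s])
        assert roc_auc_ovr(y, probs)[0] == pytest.approx(0.5, abs=0.05)

    def test_absent_class_reported_missing(self):
        probs = np.full((4, 3), 1 / 3)
        aucs = roc_auc_ovr([0, 0, 1, 1], probs)
        assert np.isnan(aucs[2])

    def test_matches_oracle_on_random_multiclass(self, rng):
        y = rng.integers(0, 3, 40)
        probs = rng.dirichlet(np.ones(3), size=40)
        aucs = roc_auc_ovr(y, probs)
        for c in range(3):
            assert aucs[c] == pytest.approx(
                auc_pair_counting(y, probs[:, c], c), abs=1e-12
            )

    def test_curve_points_monotone(self, rng):
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        pts = roc_curve_points(y, s, 1)
        assert (np.diff(pts["fpr"]) >= 0).all()
        assert (np.diff(pts["tpr"]) >= 0).all()
        assert pts["fpr"].iloc[-1] == 1.0 and pts["tpr"].iloc[-1] == 1.0


class TestMetricReport:
    def test_macro_is_unweighted_mean(self, rng):
        y_true = rng.integers(0, 3, 90)
        y_pred = rng.integers(0, 3, 90)
        rep = metric_report(y_true, y_pred, n_classes=3)
        assert rep.macro_f1 == pytest.approx(rep.per_class["f1"].mean())

    def test_accuracy_equals_agreement_fraction(self, rng):
        y_true = rng.integers(0, 3, 90)
        y_pred = rng.integers(0, 3, 90)
        rep = metric_report(y_true, y_pred, n_classes=3)
        assert rep.accuracy == pytest.approx((y_true == y_pred).mean())

    def test_perfect_predictions_all_ones(self):
        y = [0, 1, 2] * 5
        rep = metric_report(y, y, n_classes=3)
        assert rep.accuracy == rep.macro_f1 == rep.mcc == 1.0

    def test_scale_rendering(self):
        y = [0, 1, 2] * 5
        frame = metric_report(y, y, n_classes=3).to_frame(scale=100)
        assert frame["precision"].iloc[0] == 100.0

    def test_exhaustive_small_matrix_oracle(self, rng):
        """Sampled 3x3 matrices with small counts: every metric agrees with
        an independent recomputation from expanded label vectors."""
        from sklearn.metrics import matthews_corrcoef

        for _ in range(200):
            counts = rng.integers(0, 11, (3, 3))
            if counts.sum() == 0 or counts.sum(axis=0).min() == 0 \
                    or counts.sum(axis=1).min() == 0:
                continue
            y_true, y_pred = [], []
            for i in range(3):
                for j in range(3):
                    y_true += [i] * counts[i, j]
                    y_pred += [j] * counts[i, j]
            cm = _cm(counts)
            prf = per_class_prf(cm)
            for c in range(3):
                tp = counts[c, c]
                col = counts[:, c].sum()
                row = counts[c].sum()
                assert prf.iloc[c]["precision"] == pytest.approx(tp / col)
                assert prf.iloc[c]["recall"] == pytest.approx(tp / row)
            assert mcc(cm) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )


class TestCrossValidate:
    @staticmethod
    def _majority_builder(x, y, seed):
        major = np.bincount(y).argmax()

        def predict_fn(xv):
            labels = np.full(len(xv), major)
            return labels, None

        return predict_fn

    def test_folds_partition_data(self):
        y = np.repeat([0, 1, 2], 20)
        x = np.arange(60)[:, None]
        seen = []
        def builder(xtr, ytr, seed):
            def predict_fn(xv):
                seen.extend(xv[:, 0].tolist())
                return np.zeros(len(xv), dtype=int), None
            return predict_fn
        cross_validate(x, y, 5, builder, seed=0)
        assert sorted(seen) == list(range(60))

    def test_identical_folds_zero_std(self):
        y = np.repeat([0, 1, 2], 10)
        x = np.zeros((30, 1))
        _, agg = cross_validate(x, y, 5, self._majority_builder, seed=1)
        acc = agg[(agg["class_name"] == "overall") & (agg["metric"] == "accuracy")]
        assert acc["std"].iloc[0] == pytest.approx(0.0)

    def test_mean_and_sample_std_hand_case(self):
        vals = np.array([0.96, 0.98])
        assert vals.mean() == pytest.approx(0.97)
        assert vals.std(ddof=1) == pytest.approx(0.0141421, abs=1e-6)
        # the aggregator uses exactly this convention
        reports, agg = cross_validate(
            np.zeros((20, 1)), np.repeat([0, 1], 10), 2,
            self._majority_builder, seed=0,
        )
        accs = np.array([r.accuracy for r in reports])
        row = agg[(agg["class_name"] == "overall") & (agg["metric"] == "accuracy")]
        assert row["mean"].iloc[0] == pytest.approx(accs.mean())
        assert row["std"].iloc[0] == pytest.approx(accs.std(ddof=1))

    def test_deterministic_fold_assignment(self):
        y = np.repeat([0, 1, 2], 10)
        x = np.arange(30)[:, None]
        folds = []
        def builder(xtr, ytr, seed):
            folds.append(tuple(xtr[:, 0]))
            return lambda xv: (np.zeros(len(xv), dtype=int), None)
        cross_validate(x, y, 3, builder, seed=5)
        first = list(folds)
        folds.clear()
        cross_validate(x, y, 3, builder, seed=5)
        assert folds == first

    def test_small_class_warns(self):
        y = np.array([0] * 10 + [1] * 2)
        with pytest.warns(UserWarning, match="fewer samples"):
            cross_validate(np.zeros((12, 1)), y, 3, self._majority_builder, seed=0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(np.zeros((10, 1)), np.zeros(10, dtype=int), 1,
                           self._majority_builder)
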