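"""Multi-label metrics against brute-force oracles and known toys."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from mfpep.metrics import (
    MetricError,
    confusion_metrics,
    evaluate_predictions,
    roc_auc_per_class,
    set_based_metrics,
    sets_from_matrix,
)


def brute_force_set_metrics(true_sets, pred_sets, M):
    """Independent re-derivation with explicit per-sample arithmetic."""
    n = len(true_sets)
    prec = sum(
        (len(t & p) / len(p)) if p else (1.0 if not t else 0.0)
        for t, p in zip(true_sets, pred_sets)
    ) / n
    cov = sum(
        (len(t & p) / len(t)) if t else (1.0 if not p else 0.0)
        for t, p in zip(true_sets, pred_sets)
    ) / n
    acc = sum(
        (len(t & p) / len(t | p)) if (t | p) else 1.0
        for t, p in zip(true_sets, pred_sets)
    ) / n
    atrue = sum(1.0 for t, p in zip(true_sets, pred_sets) if t == p) / n
    afalse = sum(
        (len(t | p) - len(t & p)) / M for t, p in zip(true_sets, pred_sets)
    ) / n
    return prec, cov, acc, atrue, afalse


def _random_sets(rng, n, m):
    true = (rng.random((n, m)) < 0.4).astype(int)
    pred = (rng.random((n, m)) < 0.4).astype(int)
    return true, pred


class TestSetBasedMetrics:
    def test_hand_enumerated_toy(self):
        true = [{1, 2}, {3}]
        pred = [{1}, {2, 3}]
        prec, cov, acc, atrue, afalse = set_based_metrics(true, pred, M=3)
        assert prec == pytest.approx(0.75)
        assert cov == pytest.approx(0.75)
        assert acc == pytest.approx(0.5)
        assert atrue == 0.0
        assert afalse == pytest.approx(1 / 3)

    def test_perfect_prediction(self):
        sets = [{0, 1}, {2}, set()]
        out = set_based_metrics(sets, sets, M=3)
        assert out == (1.0, 1.0, 1.0, 1.0, 0.0)

    def test_all_empty_predictions_with_nonempty_truth(self):
        true = [{0}, {1, 2}]
        pred = [set(), set()]
        prec, cov, acc, atrue, _ = set_based_metrics(true, pred, M=3)
        assert (prec, cov, acc, atrue) == (0.0, 0.0, 0.0, 0.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(101)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            m = int(rng.integers(1, 7))
            T, P = _random_sets(rng, n, m)
            ts, ps = sets_from_matrix(T), sets_from_matrix(P)
            assert np.allclose(
                set_based_metrics(ts, ps, M=m), brute_force_set_metrics(ts, ps, m)
            )

    def test_ordering_invariants_hold(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            T, P = _random_sets(rng, 8, 5)
            ts, ps = sets_from_matrix(T), sets_from_matrix(P)
            prec, cov, acc, atrue, afalse = set_based_metrics(ts, ps, M=5)
            assert atrue <= acc + 1e-12
            assert acc <= min(prec, cov) + 1e-12
            assert (afalse == 0) == (atrue == 1)

    def test_union_exceeding_label_space_rejected(self):
        with pytest.raises(MetricError):
            set_based_metrics([{0, 1}], [{2}], M=2)


class TestConfusionMetrics:
    def test_hand_toy(self):
        T = np.array([[0, 1, 1], [0, 0, 1]])
        P = np.array([[0, 1, 0], [0, 1, 1]])
        f1, mcc = confusion_metrics(T, P)
        assert f1 == pytest.approx(4 / 6)
        assert mcc == pytest.approx(3 / 9)

    def test_perfect_and_inverted(self):
        T = np.array([[1, 0], [0, 1]])
        assert confusion_metrics(T, T) == (1.0, 1.0)
        f1, mcc = confusion_metrics(T, 1 - T)
        assert f1 == 0.0 and mcc == pytest.approx(-1.0)

    def test_micro_averaging_matches_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            T, P = _random_sets(rng, 10, 4)
            f1, mcc = confusion_metrics(T, P)
            assert f1 == pytest.approx(
                f1_score(T.ravel(), P.ravel(), zero_division=0)
            )
            assert mcc == pytest.approx(matthews_corrcoef(T.ravel(), P.ravel()))

    def test_non_binary_rejected(self):
        with pytest.raises(MetricError):
            confusion_metrics(np.array([[0.5]]), np.array([[1]]))


class TestROCAUC:
    def test_pairwise_concordance_toy(self):
        T = np.array([[1], [0], [1], [0]])
        S = np.array([[0.9], [0.8], [0.4], [0.2]])
        assert roc_auc_per_class(T, S)[0] == pytest.approx(0.75)

    def test_full_separation_and_all_ties(self):
        T = np.array([[1], [1], [0], [0]])
        assert roc_auc_per_class(T, np.array([[0.9], [0.8], [0.2], [0.1]]))[0] == 1.0
        assert roc_auc_per_class(T, np.full((4, 1), 0.5))[0] == 0.5

    def test_single_class_column_flagged_undefined(self):
        T = np.array([[1], [1]])
        out = roc_auc_per_class(T, np.array([[0.2], [0.9]]))
        assert np.isnan(out[0])

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n, m = 12, 3
            T = (rng.random((n, m)) < 0.5).astype(int)
            S = np.round(rng.random((n, m)), 1)  # coarse scores force ties
            mine = roc_auc_per_class(T, S)
            for c in range(m):
                if np.isnan(mine[c]):
                    assert T[:, c].min() == T[:, c].max()
                else:
                    assert mine[c] == pytest.approx(roc_auc_score(T[:, c], S[:, c]))

    def test_invariant_to_monotone_transformations(self):
        rng = np.random.default_rng(13)
        T = (rng.random((20, 2)) < 0.5).astype(int)
        T[0] = 1
        T[1] = 0
        S = rng.random((20, 2))
        a = roc_auc_per_class(T, S)
        b = roc_auc_per_class(T, np.exp(3 * S) + 7)
        assert np.allclose(a, b, equal_nan=True)


def test_evaluate_predictions_combines_all_metrics():
    T = np.array([[0, 1, 1], [0, 0, 1]])
    S = np.array([[0.1, 0.9, 0.2], [0.3, 0.8, 0.7]])
    rep = evaluate_predictions(T, S, threshold=0.5)
    assert rep.precision == pytest.approx(0.75)
    assert rep.coverage == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(4 / 6)
    assert rep.mcc == pytest.approx(3 / 9)
    d = rep.to_dict()
    assert set(d) >= {"precision", "coverage", "accuracy", "absolute_true",
                      "absolute_false", "f1", "mcc"}
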