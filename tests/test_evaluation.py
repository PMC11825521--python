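"""Metrics, fold splitting, cross-validation and channel comparison."""

import numpy as np
import pytest

from neosleep.evaluation import (
    ConfusionMatrix,
    compare_channels,
    compute_metrics,
    export_report,
    kfold_split,
    run_cv,
)
from neosleep.lstm import LSTMConfig
from neosleep.smote import SmoteConfig

FAST_LSTM = dict(max_epochs=10, patience=5)


class TestKFold:
    def test_partition_covers_all_rows(self):
        splits = kfold_split(100, k=10, seed=0)
        tests = [set(te) for _, te in splits]
        assert all(len(t) == 10 for t in tests)
        assert set().union(*tests) == set(range(100))
        for i in range(10):
            for j in range(i + 1, 10):
                assert not tests[i] & tests[j]

    def test_train_test_disjoint_and_complete(self):
        for tr, te in kfold_split(37, k=5, seed=1):
            assert not set(tr) & set(te)
            assert len(tr) + len(te) == 37

    def test_same_seed_identical(self):
        a = kfold_split(50, k=5, seed=2)
        b = kfold_split(50, k=5, seed=2)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_remainder_spread(self):
        sizes = sorted((len(te) for _, te in kfold_split(17, k=5, seed=3)), reverse=True)
        assert sizes == [4, 4, 3, 3, 3]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            kfold_split(4, k=5, seed=0)


def metrics_oracle(counts):
    """Brute-force evaluation of the six metrics from per-class
    TP/TN/FP/FN tallies over raw label pairs (independent code path)."""
    k = counts.shape[0]
    pairs = []
    for a in range(k):
        for b in range(k):
            pairs += [(a, b)] * int(counts[a, b])
    n = len(pairs)
    acc = sum(1 for a, b in pairs if a == b) / n
    # chance agreement from marginals
    pe = sum(
        (sum(1 for a, _ in pairs if a == c) / n) * (sum(1 for _, b in pairs if b == c) / n)
        for c in range(k)
    )
    kappa = 1.0 if pe >= 1 else (acc - pe) / (1 - pe)
    rec = pre = f1 = 0.0
    for c in range(k):
        tp = sum(1 for a, b in pairs if a == c and b == c)
        fn = sum(1 for a, b in pairs if a == c and b != c)
        fp = sum(1 for a, b in pairs if a != c and b == c)
        support = tp + fn
        r = tp / support if support else 0.0
        p = tp / (tp + fp) if tp + fp else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        w = support / n
        rec += w * r
        pre += w * p
        f1 += w * f
    # multiclass MCC from covariance form
    t = np.array([sum(1 for a, _ in pairs if a == c) for c in range(k)], float)
    p_ = np.array([sum(1 for _, b in pairs if b == c) for c in range(k)], float)
    c_ = sum(1 for a, b in pairs if a == b)
    num = c_ * n - t @ p_
    den = np.sqrt((n**2 - p_ @ p_) * (n**2 - t @ t))
    mcc = 0.0 if den == 0 else num / den
    return dict(accuracy=acc, kappa=kappa, recall=rec, precision=pre, mcc=mcc, f1=f1)


class TestComputeMetrics:
    def test_perfect_agreement(self):
        m = compute_metrics(ConfusionMatrix(np.diag([50] * 5), np.arange(1, 6)))
        assert m.accuracy == 1 and m.kappa == 1 and m.mcc == 1 and m.f1 == 1

    def test_binary_hand_example(self):
        # TP=40, FN=10, FP=20, TN=30 scored with the printed 2x2 formulas
        m = compute_metrics(ConfusionMatrix(np.array([[40, 10], [20, 30]]), np.array([1, 2])))
        assert m.accuracy == pytest.approx(0.7)
        kappa_2x2 = 2 * (40 * 30 - 20 * 10) / ((40 + 20) * (20 + 30) + (40 + 10) * (10 + 30))
        assert m.kappa == pytest.approx(kappa_2x2, abs=1e-12)
        mcc_2x2 = (40 * 30 - 20 * 10) / np.sqrt(60 * 50 * 50 * 40)
        assert m.mcc == pytest.approx(mcc_2x2, abs=1e-12)

    def test_uniform_matrix_chance_level(self):
        m = compute_metrics(ConfusionMatrix(np.full((5, 5), 4), np.arange(1, 6)))
        assert m.kappa == pytest.approx(0.0, abs=1e-12)
        assert m.mcc == pytest.approx(0.0, abs=1e-12)

    def test_against_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 30, size=(k, k))
            if counts.sum() == 0 or counts.sum(axis=1).min() == 0:
                continue
            m = compute_metrics(ConfusionMatrix(counts, np.arange(1, k + 1)))
            ref = metrics_oracle(counts)
            for key, v in ref.items():
                assert getattr(m, key) == pytest.approx(v, abs=1e-12), key

    def test_never_predicted_class_zero_precision(self, caplog):
        counts = np.array([[5, 0, 0], [3, 0, 2], [0, 0, 5]])
        with caplog.at_level("WARNING", logger="neosleep.evaluation"):
            m = compute_metrics(ConfusionMatrix(counts, np.arange(1, 4)))
        assert 0 <= m.precision < 1
        assert any("never predicted" in r.message for r in caplog.records)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(np.zeros((2, 2), int), np.array([1, 2])))

    def test_per_class_views_consistent(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), np.array([1, 2]))
        views = cm.per_class()
        assert list(views["TP"]) == [8, 9]
        assert list(views["FP"]) == [1, 2]
        assert list(views["FN"]) == [2, 1]
        assert list(views["TN"]) == [9, 8]


@pytest.fixture(scope="module")
def cv_result(small_features):
    c3 = small_features.select_channels(["C3"])
    return run_cv(
        c3, k=4, seed=5,
        lstm_config=LSTMConfig.reduced(seed=5, **FAST_LSTM),
        smote_config=SmoteConfig(seed=5),
        keep_artifacts=True,
    )


class TestRunCV:
    def test_fold_count_and_pooled_total(self, cv_result, small_features):
        assert len(cv_result.fold_metrics) == 4
        assert cv_result.pooled_confusion.total == small_features.n_epochs
        per_fold = sum(f.confusion.total for f in cv_result.fold_metrics)
        assert per_fold == small_features.n_epochs

    def test_summary_matches_hand_aggregation(self, cv_result):
        accs = np.array([f.accuracy for f in cv_result.fold_metrics])
        mean, sd = cv_result.summary()["accuracy"]
        assert mean == pytest.approx(accs.mean())
        assert sd == pytest.approx(accs.std())  # population convention

    def test_weighted_recall_equals_accuracy(self, cv_result):
        for f in cv_result.fold_metrics:
            assert f.recall == pytest.approx(f.accuracy, abs=1e-12)

    def test_smote_balances_every_training_fold(self, cv_result):
        for art in cv_result.artifacts:
            counts = np.unique(art.smote_y, return_counts=True)[1]
            assert counts.min() == counts.max()

    def test_metrics_within_bounds(self, cv_result):
        for f in cv_result.fold_metrics:
            for m in ("accuracy", "recall", "precision", "f1"):
                assert 0.0 <= getattr(f, m) <= 1.0
            assert -1.0 <= f.kappa <= 1.0 and -1.0 <= f.mcc <= 1.0


class TestCompareChannels:
    def test_boosted_channel_ranks_first(self, small_features):
        # C3 generated at 1.5x snr must beat T4 on shared folds
        table = compare_channels(
            small_features,
            {"C3": ("C3",), "T4": ("T4",)},
            k=3, seed=6,
            lstm_config=LSTMConfig.reduced(seed=6, **FAST_LSTM),
            smote_config=SmoteConfig(seed=6),
        )
        assert list(table.table["configuration"]) == ["C3", "T4"]
        assert table.ranking[0] == "C3"

    def test_export_report_roundtrip(self, small_features, tmp_path):
        import pandas as pd

        table = compare_channels(
            small_features,
            {"C3": ("C3",)},
            k=3, seed=7,
            lstm_config=LSTMConfig.reduced(seed=7, **FAST_LSTM),
            smote_config=SmoteConfig(seed=7),
        )
        paths = export_report(table, tmp_path / "report")
        back = pd.read_csv(paths["comparison"])
        for col in back.columns:
            if back[col].dtype.kind == "f":
                assert np.allclose(back[col], table.table[col], atol=1e-12)
        acc = pd.read_csv(paths["accuracy_series"])
        assert len(acc) == 3  # k points per configuration
        curves = pd.read_csv(paths["validation_curves"])
        for j, hist in enumerate(table.per_config["C3"].histories):
            fold_rows = curves[curves["fold"] == j]
            assert len(fold_rows) == len(hist["val_loss"])
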