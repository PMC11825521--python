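"""Cross-validated evaluation and channel-configuration comparison.

Ten-fold (by default) shuffled cross-validation over epochs; per fold
the projection is fitted on the training rows only, SMOTE balances the
projected training rows only, a fresh classifier is trained, and the
untouched test rows are scored. Six metrics are computed from the fold
confusion matrix: accuracy, Cohen's kappa, support-weighted recall /
precision / F1, and the Matthews correlation coefficient. Kappa and MCC
use the standard multiclass generalizations, which reduce exactly to the
familiar 2×2 formulas

    kappa = 2(TP·TN − FP·FN) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN))
    MCC   = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

on binary problems. Support-weighted recall equals accuracy by algebraic
identity. The channel-comparison harness runs the same folds (shared
seed) for every channel configuration and tabulates mean ± SD per
metric, ranked by mean accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lstm as lstm_mod
from .pipeline import FeatureMatrix, apply_projection, fit_projection
from .smote import SmoteConfig, class_histogram, smote_resample

__all__ = [
    "ConfusionMatrix",
    "FoldMetrics",
    "CVResult",
    "ComparisonTable",
    "kfold_split",
    "compute_metrics",
    "run_cv",
    "compare_channels",
    "export_report",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "kappa", "recall", "precision", "mcc", "f1")


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = np.asarray(self.classes)
        k = self.classes.size
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_labels(cls, true, pred, classes=None) -> "ConfusionMatrix":
        true = np.asarray(true)
        pred = np.asarray(pred)
        if classes is None:
            classes = np.unique(np.concatenate([true, pred]))
        classes = np.asarray(classes)
        index = {c: k for k, c in enumerate(classes)}
        counts = np.zeros((classes.size, classes.size), dtype=np.int64)
        for t, p in zip(true, pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> pd.DataFrame:
        """TP/FP/FN/TN per class (one-vs-rest views)."""
        tp = np.diag(self.counts)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return pd.DataFrame(
            {"class": self.classes, "TP": tp, "FP": fp, "FN": fn, "TN": tn}
        )


@dataclass
class FoldMetrics:
    accuracy: float
    kappa: float
    recall: float
    precision: float
    mcc: float
    f1: float
    confusion: ConfusionMatrix
    fold_index: int = 0

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def kfold_split(n_rows: int, k: int = 10, seed: int = 0):
    """Shuffled partition into k near-equal disjoint test sets covering
    all rows; returns [(train_idx, test_idx), ...]."""
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_rows)
    folds = np.array_split(order, k)
    out = []
    for j in range(k):
        test = np.sort(folds[j])
        train = np.sort(np.concatenate([folds[i] for i in range(k) if i != j]))
        out.append((train, test))
    return out


def compute_metrics(confusion: ConfusionMatrix, fold_index: int = 0) -> FoldMetrics:
    """The six metrics from a confusion matrix.

    A class that is never predicted has undefined precision; it
    contributes 0 to the weighted average, with a logged warning.
    """
    counts = confusion.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    row = counts.sum(axis=1)  # true-class supports
    col = counts.sum(axis=0)  # prediction counts

    accuracy = tp.sum() / total

    # Cohen's kappa, multiclass observed-vs-expected agreement
    pe = float(row @ col) / total**2
    kappa = 1.0 if pe >= 1.0 else (accuracy - pe) / (1.0 - pe)

    with np.errstate(invalid="ignore", divide="ignore"):
        rec_c = np.where(row > 0, tp / row, 0.0)
        pre_c = np.where(col > 0, tp / col, 0.0)
    never_predicted = (col == 0) & (row > 0)
    if never_predicted.any():
        logger.warning(
            "classes %s never predicted; their precision counts as 0",
            list(confusion.classes[never_predicted]),
        )
    weights = row / total
    recall = float(weights @ rec_c)
    precision = float(weights @ pre_c)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1_c = np.where(pre_c + rec_c > 0, 2 * pre_c * rec_c / (pre_c + rec_c), 0.0)
    f1 = float(weights @ f1_c)

    # multiclass MCC (R_k statistic)
    cov_yp = tp.sum() * total - float(row @ col)
    cov_yy = total**2 - float(row @ row)
    cov_pp = total**2 - float(col @ col)
    denom = np.sqrt(cov_yy * cov_pp)
    mcc = 0.0 if denom == 0 else float(cov_yp / denom)

    return FoldMetrics(
        accuracy=float(accuracy),
        kappa=float(kappa),
        recall=recall,
        precision=precision,
        mcc=mcc,
        f1=f1,
        confusion=confusion,
        fold_index=fold_index,
    )


@dataclass
class FoldArtifacts:
    """Everything fitted inside one fold (for the leakage audit and
    report layer)."""

    metrics: FoldMetrics
    projection: object
    smote_X: np.ndarray
    smote_y: np.ndarray
    model_snapshot: dict
    history: dict
    histogram_before: dict
    histogram_after: dict


def _run_fold(
    features: FeatureMatrix,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fold_index: int,
    projection_threshold: float,
    smote_config: SmoteConfig,
    lstm_config: lstm_mod.LSTMConfig,
    fold_seed: int,
    shared_projection=None,
) -> FoldArtifacts:
    """One CV fold: fit on train rows only, score untouched test rows."""
    train = FeatureMatrix(
        values=features.values[train_idx],
        feature_names=list(features.feature_names),
        labels=features.labels[train_idx],
        channel_set=list(features.channel_set),
    )
    projection = shared_projection or fit_projection(train, projection_threshold)
    z_train = apply_projection(train, projection)
    y_train = train.labels

    hist_before = class_histogram(y_train)[0]
    fold_smote = SmoteConfig(
        k_neighbors=smote_config.k_neighbors,
        delta_range=smote_config.delta_range,
        seed=smote_config.seed + fold_index,
        target_policy=smote_config.target_policy,
    )
    z_bal, y_bal = smote_resample(z_train, y_train, fold_smote)
    hist_after = class_histogram(y_bal)[0]

    import dataclasses

    fold_lstm = dataclasses.replace(lstm_config, seed=fold_seed)
    model = lstm_mod.build_model(fold_lstm, input_dim=z_bal.shape[1])
    history = lstm_mod.train(model, z_bal, y_bal, fold_lstm)

    test = FeatureMatrix(
        values=features.values[test_idx],
        feature_names=list(features.feature_names),
        labels=features.labels[test_idx],
        channel_set=list(features.channel_set),
    )
    z_test = apply_projection(test, projection)
    _, pred = lstm_mod.predict(model, z_test)
    confusion = ConfusionMatrix.from_labels(
        test.labels, pred, classes=np.arange(1, 6)
    )
    metrics = compute_metrics(confusion, fold_index=fold_index)
    logger.info(
        "fold %d: %d comps, stop epoch %d, acc %.3f (classes %s -> %s)",
        fold_index, projection.n_components_retained,
        history["stopped_epoch"], metrics.accuracy, hist_before, hist_after,
    )
    return FoldArtifacts(
        metrics=metrics,
        projection=projection,
        smote_X=z_bal,
        smote_y=y_bal,
        model_snapshot=model.snapshot(),
        history=history,
        histogram_before=hist_before,
        histogram_after=hist_after,
    )


@dataclass
class CVResult:
    fold_metrics: list[FoldMetrics]
    pooled_confusion: ConfusionMatrix
    histories: list[dict]
    artifacts: list[FoldArtifacts] | None = None

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean ± population SD of each metric over folds."""
        out = {}
        for m in METRIC_NAMES:
            values = np.array([getattr(f, m) for f in self.fold_metrics])
            out[m] = (float(values.mean()), float(values.std()))
        return out


def run_cv(
    features: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    projection_threshold: float = 0.95,
    smote_config: SmoteConfig | None = None,
    lstm_config: lstm_mod.LSTMConfig | None = None,
    paper_faithful_projection: bool = False,
    keep_artifacts: bool = False,
) -> CVResult:
    """k-fold cross-validation of the full projection→SMOTE→LSTM chain.

    By default every fold refits standardization+PCA on its own training
    rows. ``paper_faithful_projection=True`` fits one projection on all
    rows before splitting, mirroring pipelines that run PCA ahead of CV
    (and accepting the leakage that entails).
    """
    smote_config = smote_config or SmoteConfig(seed=seed)
    lstm_config = lstm_config or lstm_mod.LSTMConfig.reduced(seed=seed)
    splits = kfold_split(features.n_epochs, k=k, seed=seed)
    shared = fit_projection(features, projection_threshold) if paper_faithful_projection else None

    fold_metrics, histories, artifacts = [], [], []
    pooled = np.zeros((5, 5), dtype=np.int64)
    for j, (train_idx, test_idx) in enumerate(splits):
        art = _run_fold(
            features, train_idx, test_idx, j,
            projection_threshold, smote_config, lstm_config,
            fold_seed=seed * 1000 + j,
            shared_projection=shared,
        )
        fold_metrics.append(art.metrics)
        histories.append(art.history)
        pooled += art.metrics.confusion.counts
        if keep_artifacts:
            artifacts.append(art)
    return CVResult(
        fold_metrics=fold_metrics,
        pooled_confusion=ConfusionMatrix(pooled, np.arange(1, 6)),
        histories=histories,
        artifacts=artifacts if keep_artifacts else None,
    )


@dataclass
class ComparisonTable:
    """Mean ± SD of the six metrics per channel configuration."""

    table: pd.DataFrame
    per_config: dict[str, CVResult] = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        """Configurations sorted by decreasing mean accuracy."""
        return list(
            self.table.sort_values("accuracy_mean", ascending=False)["configuration"]
        )


DEFAULT_CONFIGURATIONS: dict[str, tuple[str, ...]] = {
    "F3": ("F3",), "F4": ("F4",), "C3": ("C3",), "C4": ("C4",),
    "P3": ("P3",), "P4": ("P4",), "T3": ("T3",), "T4": ("T4",),
    "Left": ("F3", "C3", "P3", "T3"),
    "Right": ("F4", "C4", "P4", "T4"),
}


def compare_channels(
    features: FeatureMatrix,
    configurations: dict[str, tuple[str, ...]] | None = None,
    k: int = 10,
    seed: int = 0,
    **cv_kwargs,
) -> ComparisonTable:
    """Run identical CV folds for every channel configuration and
    tabulate mean ± SD of all six metrics.

    ``features`` must contain all channels any configuration needs; the
    per-configuration matrices are column subsets, so every run sees the
    same epochs and (same seed) the same fold splits.
    """
    configurations = configurations or DEFAULT_CONFIGURATIONS
    if len(set(configurations)) != len(configurations):
        raise ValueError("configuration names must be unique")
    rows = []
    per_config = {}
    for name, channels in configurations.items():
        sub = features.select_channels(list(channels))
        result = run_cv(sub, k=k, seed=seed, **cv_kwargs)
        per_config[name] = result
        row = {"configuration": name, "channels": "+".join(channels)}
        for metric, (mean, sd) in result.summary().items():
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sd"] = sd
        rows.append(row)
        logger.info("configuration %s: acc %.3f ± %.3f", name, row["accuracy_mean"], row["accuracy_sd"])
    table = pd.DataFrame(rows)
    return ComparisonTable(table=table, per_config=per_config)


def export_report(
    comparison: ComparisonTable,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the comparison table, per-fold metrics, pooled confusion
    matrices, accuracy-vs-fold series and validation curves as CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["comparison"] = out / "comparison.csv"
    comparison.table.to_csv(paths["comparison"], index=False, float_format="%.17g")

    fold_rows, acc_rows, curve_rows, conf_rows = [], [], [], []
    for name, result in comparison.per_config.items():
        for fm in result.fold_metrics:
            fold_rows.append({"configuration": name, "fold": fm.fold_index, **fm.as_dict()})
            acc_rows.append(
                {"configuration": name, "fold": fm.fold_index, "accuracy": fm.accuracy}
            )
        for j, hist in enumerate(result.histories):
            for e, (vl, va) in enumerate(zip(hist["val_loss"], hist["val_accuracy"])):
                curve_rows.append(
                    {
                        "configuration": name, "fold": j, "epoch": e + 1,
                        "val_loss": vl, "val_accuracy": va,
                    }
                )
        cm = result.pooled_confusion
        for a, true_c in enumerate(cm.classes):
            for b, pred_c in enumerate(cm.classes):
                conf_rows.append(
                    {
                        "configuration": name, "true": int(true_c),
                        "predicted": int(pred_c), "count": int(cm.counts[a, b]),
                    }
                )
    for key, rows in (
        ("fold_metrics", fold_rows),
        ("accuracy_series", acc_rows),
        ("validation_curves", curve_rows),
        ("pooled_confusions", conf_rows),
    ):
        paths[key] = out / f"{key}.csv"
        pd.DataFrame(rows).to_csv(paths[key], index=False, float_format="%.17g")
    return paths
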