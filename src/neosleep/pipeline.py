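"""Feature-matrix assembly and PCA reduction.

``build_features`` turns an :class:`~neosleep.recording.EpochSet` into an
epochs × features matrix with 94 named features per channel (30
time-domain + 64 frequency-domain, channel-prefixed names such as
``C3.dfa_alpha``). ``fit_projection`` z-scores the columns and fits a
PCA keeping the smallest component count whose cumulative explained
variance reaches the threshold (0.95 by default). Fitting on the
training fold only — the default — keeps test rows out of the means,
scales and components; a ``fit`` on all rows before cross-validation can
be requested explicitly to mirror pipelines that accept that leakage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .features_freq import FREQ_FEATURE_NAMES, extract_freq_features
from .features_time import TIME_FEATURE_NAMES, extract_time_features
from .recording import EpochSet

__all__ = [
    "PER_CHANNEL_FEATURE_NAMES",
    "FeatureMatrix",
    "ProjectionModel",
    "extract_channel_features",
    "build_features",
    "fit_projection",
    "apply_projection",
    "feature_manifest",
]

logger = logging.getLogger(__name__)

#: the 94 per-channel feature names, extraction order (30 time + 64 freq)
PER_CHANNEL_FEATURE_NAMES: tuple[str, ...] = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES


def extract_channel_features(x: np.ndarray, fs: float) -> np.ndarray:
    """The 94 features of one single-channel epoch, in
    :data:`PER_CHANNEL_FEATURE_NAMES` order."""
    feats = extract_time_features(x)
    feats.update(extract_freq_features(x, fs))
    return np.array([feats[name] for name in PER_CHANNEL_FEATURE_NAMES])


@dataclass
class FeatureMatrix:
    """Epochs × named features, with channel provenance in the names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    channel_set: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (self.labels.size, len(self.feature_names)):
            raise ValueError("values shape inconsistent with names/labels")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def select_channels(self, names: list[str]) -> "FeatureMatrix":
        """Column subset for a channel configuration (order preserved
        per requested channel)."""
        missing = [n for n in names if n not in self.channel_set]
        if missing:
            raise ValueError(f"channels {missing} not in {self.channel_set}")
        cols, kept = [], []
        for ch in names:
            for f in PER_CHANNEL_FEATURE_NAMES:
                name = f"{ch}.{f}"
                cols.append(self.feature_names.index(name))
                kept.append(name)
        return FeatureMatrix(
            values=self.values[:, cols],
            feature_names=kept,
            labels=self.labels.copy(),
            channel_set=list(names),
            subject_ids=list(self.subject_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df


def build_features(
    epochs: EpochSet,
    channel_set: list[str] | None = None,
    progress: bool = False,
) -> FeatureMatrix:
    """Per-epoch concatenation of each channel's 94 features.

    Deterministic given the input; any feature failure is re-raised with
    the epoch/channel context attached.
    """
    channel_set = list(channel_set or epochs.channel_names)
    idx = []
    for ch in channel_set:
        if ch not in epochs.channel_names:
            raise ValueError(f"channel {ch!r} not in {epochs.channel_names}")
        idx.append(epochs.channel_names.index(ch))

    n = epochs.n_epochs
    values = np.empty((n, 94 * len(channel_set)))
    for e in range(n):
        if progress and e % 50 == 0:
            logger.info("features: epoch %d / %d", e, n)
        for c, ch_idx in enumerate(idx):
            try:
                values[e, c * 94 : (c + 1) * 94] = extract_channel_features(
                    epochs.epochs[e, ch_idx], epochs.fs
                )
            except Exception as err:  # attach context, keep the cause
                raise RuntimeError(
                    f"feature extraction failed at epoch {e}, "
                    f"channel {channel_set[c]}: {err}"
                ) from err
    names = [f"{ch}.{f}" for ch in channel_set for f in PER_CHANNEL_FEATURE_NAMES]
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=epochs.labels.copy(),
        channel_set=channel_set,
        subject_ids=list(epochs.subject_ids),
    )


@dataclass
class ProjectionModel:
    """Fitted standardization + PCA state."""

    feature_names: list[str]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    components: np.ndarray  # n_retained x n_features, orthonormal rows
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    variance_threshold: float

    @property
    def n_components_retained(self) -> int:
        return self.components.shape[0]

    # ---- serialization: delimited tables + small JSON metadata ----

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean": self.feature_means,
                "scale": self.feature_scales,
            }
        ).to_csv(out / "scaling.csv", index=False, float_format="%.17g")
        pd.DataFrame(self.components, columns=self.feature_names).to_csv(
            out / "components.csv", index=False, float_format="%.17g"
        )
        meta = {
            "variance_threshold": self.variance_threshold,
            "n_components_retained": self.n_components_retained,
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        (out / "projection.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ProjectionModel":
        src = Path(in_dir)
        scaling = pd.read_csv(src / "scaling.csv")
        components = pd.read_csv(src / "components.csv")
        meta = json.loads((src / "projection.json").read_text())
        return cls(
            feature_names=list(scaling["feature"]),
            feature_means=scaling["mean"].to_numpy(),
            feature_scales=scaling["scale"].to_numpy(),
            components=components.to_numpy(),
            explained_variance_ratio=np.array(meta["explained_variance_ratio"]),
            explained_variance=np.array(meta["explained_variance"]),
            variance_threshold=meta["variance_threshold"],
        )


def fit_projection(train: FeatureMatrix, threshold: float = 0.95) -> ProjectionModel:
    """Z-score standardization followed by PCA retaining the smallest
    component count whose cumulative explained-variance ratio reaches
    ``threshold``. Zero-variance columns get scale 1 (they contribute
    nothing to the PCA)."""
    if train.n_epochs < 2:
        raise ValueError("need at least 2 rows to fit a projection")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    scaler = StandardScaler().fit(train.values)  # zero-variance -> scale 1
    z = scaler.transform(train.values)
    pca = PCA(n_components=None, svd_solver="full").fit(z)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    n_keep = min(n_keep, pca.components_.shape[0])
    logger.info(
        "projection: retaining %d / %d components (cum EVR %.4f)",
        n_keep, pca.components_.shape[0], cumulative[n_keep - 1],
    )
    return ProjectionModel(
        feature_names=list(train.feature_names),
        feature_means=scaler.mean_.copy(),
        feature_scales=scaler.scale_.copy(),
        components=pca.components_[:n_keep].copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:n_keep].copy(),
        explained_variance=pca.explained_variance_[:n_keep].copy(),
        variance_threshold=threshold,
    )


def apply_projection(features: FeatureMatrix, model: ProjectionModel) -> np.ndarray:
    """Project a feature matrix into the retained component space.

    Columns are realigned by name first; names that do not match the
    training names exactly raise with the differences listed.
    """
    if features.feature_names != model.feature_names:
        extra = set(features.feature_names) - set(model.feature_names)
        missing = set(model.feature_names) - set(features.feature_names)
        if extra or missing:
            raise ValueError(
                f"feature-name mismatch: missing={sorted(missing)[:5]}, "
                f"unexpected={sorted(extra)[:5]}"
            )
        order = [features.feature_names.index(n) for n in model.feature_names]
        values = features.values[:, order]
    else:
        values = features.values
    z = (values - model.feature_means) / model.feature_scales
    return z @ model.components.T


def feature_manifest() -> pd.DataFrame:
    """Name, domain and band of every per-channel feature."""
    rows = []
    for name in PER_CHANNEL_FEATURE_NAMES:
        if name in TIME_FEATURE_NAMES:
            domain = "time"
            band = ""
            if name.startswith(("sig_", "d1_", "d2_")):
                definition = "summary statistic of the signal or a derivative"
            elif name == "dfa_alpha":
                definition = "detrended fluctuation analysis scaling exponent"
            elif name == "lyap_lambda":
                definition = "largest Lyapunov exponent (Rosenstein), nats/sample"
            else:
                definition = "multiscale fluctuation entropy, nats"
        else:
            domain = "frequency"
            band = name.split("_")[0] if name.split("_")[0] in (
                "delta", "theta", "alpha", "beta") else ""
            if "norm_power" in name:
                definition = "band power / total power (trapezoidal)"
            elif "avg_freq" in name:
                definition = "PSD-weighted mean frequency in band (Hz)"
            elif "max_power" in name:
                definition = "largest PSD value in band"
            elif name.startswith("ratio_"):
                definition = "ratio of normalized band powers"
            elif name.startswith("fft_top"):
                definition = "ranked positive-frequency FFT magnitude"
            else:
                definition = "statistic of in-band Welch PSD values"
        rows.append({"name": name, "domain": domain, "band": band, "definition": definition})
    return pd.DataFrame(rows)
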