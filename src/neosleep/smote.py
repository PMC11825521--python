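"""Synthetic minority oversampling (SMOTE) for the training fold.

Each minority class is augmented to majority parity by interpolating
between a randomly chosen class member x_i and one of its k nearest
same-class neighbours x̂ (Euclidean metric):

    x_new = x_i + (x̂ − x_i) · δ,   δ ~ Uniform[0, 1]

Originals are preserved verbatim; synthetic rows lie on the connecting
segments and therefore inside the class's convex hull. The evaluation
module only ever feeds training rows in — applying this to test data
would leak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote_resample", "class_histogram"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    delta_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    target_policy: str = "match-majority"

    def validate(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        lo, hi = self.delta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("delta_range must be a sub-interval of [0, 1]")
        if self.target_policy != "match-majority":
            raise ValueError(f"unknown target_policy {self.target_policy!r}")


def class_histogram(labels: np.ndarray) -> tuple[dict[int, int], float]:
    """Label counts and the max/min imbalance ratio."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    values, counts = np.unique(labels, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    return hist, float(counts.max() / counts.min())


def smote_resample(
    features: np.ndarray,
    labels: np.ndarray,
    config: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every non-majority class to majority parity.

    Returns (features, labels) with the original rows first, unchanged,
    followed by the synthetic rows. Reproducible from ``config.seed``.
    A class with fewer than 2 members cannot be interpolated and raises;
    for 2 ≤ size ≤ k the neighbour count is lowered with a warning.
    """
    config = config or SmoteConfig()
    config.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    hist, _ = class_histogram(y)
    majority = max(hist.values())
    rng = np.random.default_rng(config.seed)
    lo, hi = config.delta_range

    new_rows, new_labels = [], []
    for cls in sorted(hist):
        deficit = majority - hist[cls]
        if deficit == 0:
            continue
        if hist[cls] < 2:
            raise ValueError(
                f"class {cls} has {hist[cls]} member(s); need >= 2 to interpolate"
            )
        k = config.k_neighbors
        if hist[cls] <= k:
            k = hist[cls] - 1
            logger.warning(
                "class %s has %d members <= k=%d; lowering k to %d",
                cls, hist[cls], config.k_neighbors, k,
            )
        members = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(members)
        neighbor_idx = nn.kneighbors(members, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, members.shape[0], size=deficit)
        pick = rng.integers(0, k, size=deficit)
        delta = rng.uniform(lo, hi, size=deficit)
        x_i = members[base]
        x_hat = members[neighbor_idx[base, pick]]
        new_rows.append(x_i + (x_hat - x_i) * delta[:, None])
        new_labels.append(np.full(deficit, cls, dtype=y.dtype))

    if not new_rows:
        return X.copy(), y.copy()
    X_out = np.vstack([X] + new_rows)
    y_out = np.concatenate([y] + new_labels)
    logger.info("SMOTE: %s -> %s", hist, class_histogram(y_out)[0])
    return X_out, y_out
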