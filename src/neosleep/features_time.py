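"""Time-domain features of a single-channel EEG epoch.

Thirty features per channel-epoch: nine summary statistics of the raw
signal and of its first and second discrete derivatives (27), plus three
nonlinear descriptors — the detrended-fluctuation-analysis scaling
exponent, the largest Lyapunov exponent estimated with the Rosenstein
nearest-neighbour divergence method, and a multiscale fluctuation
entropy.

Conventions (documented because textbooks differ): variance and standard
deviation use the population divisor ``N``; skewness is Fisher–Pearson;
kurtosis is *excess* kurtosis (normal → 0); skewness and kurtosis of a
zero-variance vector are defined as 0 rather than NaN so that flat
epochs do not poison a feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial import cKDTree

__all__ = [
    "STAT_NAMES",
    "TIME_FEATURE_NAMES",
    "DFAResult",
    "LyapunovResult",
    "MFEResult",
    "stat_descriptors",
    "derivative_stats",
    "dfa",
    "lyapunov",
    "mfe",
    "extract_time_features",
]

#: the nine summary statistics, in fixed order
STAT_NAMES = (
    "mean",
    "median",
    "std",
    "min",
    "max",
    "kurtosis",
    "skewness",
    "variance",
    "range",
)

#: all 30 time-domain feature names, in extraction order
TIME_FEATURE_NAMES = tuple(
    [f"{prefix}_{s}" for prefix in ("sig", "d1", "d2") for s in STAT_NAMES]
    + ["dfa_alpha", "lyap_lambda", "mfe"]
)


def stat_descriptors(x: np.ndarray) -> dict[str, float]:
    """Nine summary statistics of ``x``.

    Returns a dict keyed by :data:`STAT_NAMES` in order. Population
    variance/std; excess kurtosis; Fisher–Pearson skewness; the 0/0 case
    of skewness and kurtosis on a constant vector maps to 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("stat_descriptors requires a 1-D signal of length >= 2")
    var = float(np.var(x))
    if var > 0.0:
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
        skew = float(sps.skew(x, bias=True))
    else:
        kurt = 0.0
        skew = 0.0
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": float(np.sqrt(var)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "kurtosis": kurt,
        "skewness": skew,
        "variance": var,
        "range": float(np.ptp(x)),
    }


def derivative_stats(x: np.ndarray) -> dict[str, float]:
    """27 statistics: the nine descriptors of x, diff(x) and diff(diff(x)).

    Keys are prefixed ``sig_``, ``d1_`` and ``d2_``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("derivative_stats requires a 1-D signal of length >= 3")
    out: dict[str, float] = {}
    for prefix, series in (("sig", x), ("d1", np.diff(x)), ("d2", np.diff(x, n=2))):
        for name, value in stat_descriptors(series).items():
            out[f"{prefix}_{name}"] = value
    return out


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------


@dataclass
class DFAResult:
    """Scaling exponent and the intermediate quantities that produced it.

    ``alpha`` is the least-squares slope of log F(n) against log n, where
    F(n) is the RMS deviation of the integrated profile Y from its
    per-window linear trend over non-overlapping windows of length n.
    alpha ≈ 0.5 for uncorrelated noise, ≈ 1.5 for a random walk.
    """

    alpha: float
    window_sizes: np.ndarray
    fluctuations: np.ndarray
    profile: np.ndarray
    local_trend: np.ndarray = field(repr=False, default=None)


def _default_dfa_windows(n: int, n_sizes: int = 12, min_size: int = 16) -> np.ndarray:
    max_size = n // 4
    if max_size < min_size:
        raise ValueError(
            f"signal of length {n} too short for DFA: need >= {4 * min_size} samples"
        )
    sizes = np.unique(
        np.round(np.geomspace(min_size, max_size, n_sizes)).astype(int)
    )
    return sizes


def _window_fluctuation(profile: np.ndarray, n: int) -> tuple[float, np.ndarray]:
    """RMS residual of per-window linear detrending at window size n."""
    n_win = profile.size // n
    seg = profile[: n_win * n].reshape(n_win, n)
    t = np.arange(n, dtype=float)
    t_mean = t.mean()
    t_c = t - t_mean
    denom = float(np.sum(t_c**2))
    slopes = seg @ t_c / denom
    intercepts = seg.mean(axis=1) - slopes * t_mean
    trend = slopes[:, None] * t[None, :] + intercepts[:, None]
    resid = seg - trend
    return float(np.sqrt(np.mean(resid**2))), trend.ravel()


def dfa(x: np.ndarray, window_sizes: np.ndarray | None = None) -> DFAResult:
    """Detrended fluctuation analysis of a 1-D signal.

    Integrates the mean-removed signal into the profile Y, detrends Y in
    non-overlapping windows of each size n by a linear fit, and regresses
    log RMS fluctuation on log n. Window sizes default to 12 log-spaced
    values from 16 samples to len(x)/4.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dfa requires a 1-D signal")
    if window_sizes is None:
        sizes = _default_dfa_windows(x.size)
    else:
        sizes = np.asarray(window_sizes, dtype=int)
        if sizes.size < 2:
            raise ValueError("need at least two window sizes")
        if sizes.max() * 2 > x.size:
            raise ValueError("largest DFA window must fit at least twice")
    profile = np.cumsum(x - x.mean())
    flucts = np.empty(sizes.size)
    trend_smallest = None
    for j, n in enumerate(sizes):
        flucts[j], trend = _window_fluctuation(profile, int(n))
        if j == 0:
            trend_smallest = trend
    if np.any(flucts == 0.0):
        raise ValueError("zero fluctuation: constant (or piecewise-linear) input")
    alpha = float(np.polyfit(np.log(sizes), np.log(flucts), 1)[0])
    return DFAResult(
        alpha=alpha,
        window_sizes=sizes,
        fluctuations=flucts,
        profile=profile,
        local_trend=trend_smallest,
    )


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein nearest-neighbour divergence)
# ---------------------------------------------------------------------------


@dataclass
class LyapunovResult:
    """Largest Lyapunov exponent in nats per sample.

    ``divergence`` holds the mean log separation of initially-near
    trajectory pairs at each of ``n_steps`` forward steps; lambda_ is the
    mean over pairs and steps of log(d(n+1)/d(n)).
    """

    lambda_: float
    embedding_dim: int
    lag: int
    divergence: np.ndarray
    n_steps: int


def _median_frequency_period(x: np.ndarray) -> int:
    """Mean-period estimate (samples) from the median spectral frequency."""
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size)  # cycles per sample
    spec[0] = 0.0
    total = spec.sum()
    if total <= 0.0:
        return 1
    median_f = freqs[np.searchsorted(np.cumsum(spec), 0.5 * total)]
    if median_f <= 0.0:
        return 1
    return max(1, int(round(1.0 / median_f)))


def lyapunov(
    x: np.ndarray,
    embedding_dim: int = 10,
    lag: int = 20,
    n_steps: int = 300,
    theiler: int | None = None,
    max_pairs: int = 1000,
    candidate_stride: int = 2,
    query_eps: float = 0.5,
) -> LyapunovResult:
    """Largest Lyapunov exponent of a scalar series.

    Delay-embeds ``x`` with dimension ``embedding_dim`` and lag ``lag``
    (samples); for up to ``max_pairs`` reference points finds the nearest
    neighbour at least ``theiler`` samples away in time (default: one
    mean period estimated from the median FFT frequency); follows each
    pair for ``n_steps`` steps and averages the per-step log distance
    ratios. Positive values indicate exponential divergence (chaos);
    periodic signals give values near or below zero.

    The divergence estimate only needs a *near* neighbour, not the exact
    nearest, so neighbour candidates are taken from every
    ``candidate_stride``-th embedded point and the k-d tree search is
    allowed a (1 + ``query_eps``) distance slack, keeping the search
    cheap and fully deterministic.
    """
    x = np.asarray(x, dtype=float)
    min_len = (embedding_dim - 1) * lag + n_steps + 2
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} too short to embed: need >= {min_len} "
            f"samples for m={embedding_dim}, lag={lag}, n_steps={n_steps}"
        )
    if theiler is None:
        theiler = _median_frequency_period(x)

    m_points = x.size - (embedding_dim - 1) * lag
    emb = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(x, (embedding_dim - 1) * lag + 1)[
            :, ::lag
        ]
    )
    assert emb.shape == (m_points, embedding_dim)

    # pairs must be trackable for n_steps: restrict candidates accordingly
    usable = m_points - n_steps
    if usable < 2:
        raise ValueError("n_steps too large for this series length")
    stride = max(1, int(candidate_stride))
    cand_idx = np.arange(0, usable, stride)
    tree = cKDTree(emb[cand_idx], balanced_tree=False)
    refs = np.unique(np.linspace(0, usable - 1, min(max_pairs, usable)).astype(int))

    def _first_valid(i: int, cols, dist_row) -> int | None:
        for col, dist in zip(cols, dist_row):
            j = int(cand_idx[col])
            if abs(j - i) > theiler and dist > 0.0:
                return j
        return None

    k = min(cand_idx.size, 8)
    dists, idx = tree.query(emb[refs], k=k, eps=query_eps)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]

    pair_i, pair_j = [], []
    for row, i in enumerate(refs):
        j = _first_valid(int(i), idx[row], dists[row])
        if j is None and k < cand_idx.size:
            # rare: all k nearest are inside the Theiler window
            d2, i2 = tree.query(emb[i], k=min(cand_idx.size, 4 * k + 8), eps=query_eps)
            j = _first_valid(int(i), np.atleast_1d(i2), np.atleast_1d(d2))
        if j is not None:
            pair_i.append(int(i))
            pair_j.append(j)
    if not pair_i:
        raise ValueError("no valid neighbour pairs outside the Theiler window")
    pi = np.asarray(pair_i)
    pj = np.asarray(pair_j)

    # d[:, n] = distance between the two trajectories after n steps.
    # Embedding coordinates are lagged samples of the same scalar series,
    # so squared distances are sums of m shifted scalar squared diffs.
    span = (embedding_dim - 1) * lag
    offsets = np.arange(span + n_steps + 1)
    dx2 = (x[pi[:, None] + offsets] - x[pj[:, None] + offsets]) ** 2
    d2 = np.zeros((pi.size, n_steps + 1))
    for q in range(embedding_dim):
        d2 += dx2[:, q * lag : q * lag + n_steps + 1]
    log_d = 0.5 * np.log(np.maximum(d2, 1e-300))
    divergence = log_d.mean(axis=0)
    ratios = np.diff(log_d, axis=1)  # log(d(n+1)/d(n))
    lam = float(ratios.mean())
    return LyapunovResult(
        lambda_=lam,
        embedding_dim=embedding_dim,
        lag=lag,
        divergence=divergence,
        n_steps=n_steps,
    )


# ---------------------------------------------------------------------------
# multiscale fluctuation entropy
# ---------------------------------------------------------------------------


@dataclass
class MFEResult:
    """Mean over scales of the Shannon entropy of segment fluctuations."""

    value: float
    per_scale: np.ndarray
    K: int
    bins: int
    segment_length: int


def _shannon_entropy_nats(values: np.ndarray, bins: int) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 1e-12 * max(1.0, abs(hi)):
        return 0.0  # all fluctuations (numerically) identical -> single occupied bin
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def mfe(
    x: np.ndarray,
    K: int = 5,
    segment_length: int = 250,
    bins: int = 10,
) -> MFEResult:
    """Multiscale fluctuation entropy, in nats.

    At scale k the signal is cut into non-overlapping segments of
    k × segment_length samples; each segment's fluctuation is its
    standard deviation relative to its mean absolute level; H_k is the
    Shannon entropy of the fluctuation values discretized into ``bins``
    equal-width bins over their observed range; the MFE is the mean of
    H_k over k = 1..K. A constant signal has zero fluctuation at every
    scale and therefore MFE = 0.
    """
    x = np.asarray(x, dtype=float)
    per_scale = np.empty(K)
    for k in range(1, K + 1):
        seg_len = k * segment_length
        n_seg = x.size // seg_len
        if n_seg < 2:
            raise ValueError(
                f"scale {k}: fewer than 2 segments of {seg_len} samples "
                f"in a series of length {x.size}"
            )
        seg = x[: n_seg * seg_len].reshape(n_seg, seg_len)
        std = seg.std(axis=1)
        level = np.abs(seg).mean(axis=1)
        fluct = np.divide(std, level, out=np.zeros_like(std), where=level > 0)
        per_scale[k - 1] = _shannon_entropy_nats(fluct, bins)
    return MFEResult(
        value=float(per_scale.mean()),
        per_scale=per_scale,
        K=K,
        bins=bins,
        segment_length=segment_length,
    )


def extract_time_features(
    x: np.ndarray,
    dfa_windows: np.ndarray | None = None,
    lyap_kwargs: dict | None = None,
    mfe_kwargs: dict | None = None,
) -> dict[str, float]:
    """All 30 time-domain features of one epoch, keyed by
    :data:`TIME_FEATURE_NAMES`."""
    out = derivative_stats(x)
    out["dfa_alpha"] = dfa(x, dfa_windows).alpha
    out["lyap_lambda"] = lyapunov(x, **(lyap_kwargs or {})).lambda_
    out["mfe"] = mfe(x, **(mfe_kwargs or {})).value
    return out
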