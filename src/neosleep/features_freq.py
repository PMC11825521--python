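"""Frequency-domain features of a single-channel EEG epoch.

Sixty-four features per channel-epoch, all derived from a Welch power
spectral density estimate and a raw FFT magnitude spectrum:

* 36 central-tendency statistics of the in-band PSD values (9 per band
  over delta 0.5–3 Hz, theta 4–7 Hz, alpha 8–12 Hz, beta 13–30 Hz);
* 4 normalized band powers (band power / total power, trapezoidal);
* 4 power-weighted average frequencies;
* 4 maximum in-band PSD values;
* 6 ratios of normalized band powers (delta/theta, alpha/beta,
  delta/alpha, theta/beta, delta/beta, theta/alpha);
* the 10 largest positive-frequency FFT magnitudes, sorted descending.

Band intervals are closed; spectrum bins falling in the printed gaps
(3–4, 7–8, 12–13 Hz) belong to no band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "Band",
    "Spectrum",
    "DEFAULT_BANDS",
    "BAND_STAT_NAMES",
    "RATIO_NAMES",
    "FREQ_FEATURE_NAMES",
    "welch_psd",
    "band_central_tendency",
    "band_norm_power",
    "band_avg_frequency",
    "band_max_power",
    "band_ratios",
    "fft_top10",
    "extract_freq_features",
]

logger = logging.getLogger(__name__)

#: guard added to ratio denominators so degenerate spectra stay finite
RATIO_EPS = 1e-12


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi")


DEFAULT_BANDS = (
    Band("delta", 0.5, 3.0),
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 13.0, 30.0),
)

BAND_STAT_NAMES = (
    "mean",
    "median",
    "mode",
    "variance",
    "std",
    "kurtosis",
    "skewness",
    "min",
    "max",
)

RATIO_NAMES = (
    "ratio_delta_theta",
    "ratio_alpha_beta",
    "ratio_delta_alpha",
    "ratio_theta_beta",
    "ratio_delta_beta",
    "ratio_theta_alpha",
)

_RATIO_PAIRS = (
    ("delta", "theta"),
    ("alpha", "beta"),
    ("delta", "alpha"),
    ("theta", "beta"),
    ("delta", "beta"),
    ("theta", "alpha"),
)


def _freq_feature_names() -> tuple[str, ...]:
    names: list[str] = []
    for band in DEFAULT_BANDS:
        names += [f"{band.name}_{s}" for s in BAND_STAT_NAMES]
    names += [f"{band.name}_norm_power" for band in DEFAULT_BANDS]
    names += [f"{band.name}_avg_freq" for band in DEFAULT_BANDS]
    names += [f"{band.name}_max_power" for band in DEFAULT_BANDS]
    names += list(RATIO_NAMES)
    names += [f"fft_top{i + 1}" for i in range(10)]
    return tuple(names)


#: all 64 frequency-domain feature names, in extraction order
FREQ_FEATURE_NAMES = _freq_feature_names()


@dataclass
class Spectrum:
    """Welch PSD on a frequency grid, with estimation metadata."""

    freqs: np.ndarray
    psd: np.ndarray
    nperseg: int
    noverlap: int
    window: str


def welch_psd(
    x: np.ndarray,
    fs: float,
    nperseg: int = 1000,
    noverlap: int | None = None,
    window: str = "hann",
) -> Spectrum:
    """Welch power spectral density: averaged Hann-windowed modified
    periodograms over 50 %-overlapping segments (2 s at 500 Hz)."""
    x = np.asarray(x, dtype=float)
    if noverlap is None:
        noverlap = nperseg // 2
    if x.size < 2 * nperseg:
        raise ValueError(
            f"welch_psd needs >= {2 * nperseg} samples, got {x.size}"
        )
    freqs, psd = sps.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    return Spectrum(freqs=freqs, psd=psd, nperseg=nperseg, noverlap=noverlap, window=window)


def _band_mask(spec: Spectrum, band: Band) -> np.ndarray:
    mask = (spec.freqs >= band.lo) & (spec.freqs <= band.hi)
    if not np.any(mask):
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz is empty on this grid")
    return mask


def _histogram_mode(values: np.ndarray, n_bins: int = 10) -> float:
    """Mode of continuous values: midpoint of the most populated of
    ``n_bins`` equal-width bins (ties broken toward the lowest bin)."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return lo
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    best = int(np.argmax(counts))  # argmax returns first maximum = lowest bin
    return float(0.5 * (edges[best] + edges[best + 1]))


def band_central_tendency(spec: Spectrum, band: Band, mode_bins: int = 10) -> dict[str, float]:
    """Nine statistics of the PSD values inside a band, keys prefixed
    by the band name. Population variance/std, excess kurtosis."""
    values = spec.psd[_band_mask(spec, band)]
    var = float(np.var(values))
    if var > 0.0:
        kurt = float(spstats.kurtosis(values, fisher=True, bias=True))
        skew = float(spstats.skew(values, bias=True))
    else:
        kurt = 0.0
        skew = 0.0
    return {
        f"{band.name}_mean": float(np.mean(values)),
        f"{band.name}_median": float(np.median(values)),
        f"{band.name}_mode": _histogram_mode(values, mode_bins),
        f"{band.name}_variance": var,
        f"{band.name}_std": float(np.sqrt(var)),
        f"{band.name}_kurtosis": kurt,
        f"{band.name}_skewness": skew,
        f"{band.name}_min": float(np.min(values)),
        f"{band.name}_max": float(np.max(values)),
    }


def band_norm_power(spec: Spectrum, band: Band) -> float:
    """Trapezoidal band power divided by trapezoidal total power."""
    total = float(np.trapezoid(spec.psd, spec.freqs))
    if total <= 0.0:
        raise ValueError("zero total power")
    mask = _band_mask(spec, band)
    band_power = float(np.trapezoid(spec.psd[mask], spec.freqs[mask]))
    return band_power / total


def band_avg_frequency(spec: Spectrum, band: Band) -> float:
    """PSD-weighted mean frequency within the band (Hz)."""
    mask = _band_mask(spec, band)
    weight = float(np.sum(spec.psd[mask]))
    if weight <= 0.0:
        raise ValueError(f"zero power in band {band.name}")
    return float(np.sum(spec.freqs[mask] * spec.psd[mask]) / weight)


def band_max_power(spec: Spectrum, band: Band) -> float:
    """Largest PSD value within the band."""
    return float(np.max(spec.psd[_band_mask(spec, band)]))


def band_ratios(norm_powers: dict[str, float]) -> dict[str, float]:
    """The six ratios of normalized band powers, denominator guarded by
    ``RATIO_EPS`` so degenerate inputs stay finite."""
    out: dict[str, float] = {}
    for name, (num, den) in zip(RATIO_NAMES, _RATIO_PAIRS):
        value = norm_powers[num] / (norm_powers[den] + RATIO_EPS)
        if value > 1e6:
            logger.warning("band ratio %s = %.3g: near-zero denominator %s", name, value, den)
        out[name] = value
    return out


def fft_top10(x: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Magnitudes of the 10 largest positive-frequency FFT bins,
    sorted descending. The DC bin is excluded."""
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("fft_top10 requires at least 20 samples")
    mags = np.abs(np.fft.rfft(x))[1:]  # drop DC
    top = np.sort(mags)[::-1][:10]
    return top


def extract_freq_features(
    x: np.ndarray,
    fs: float,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    nperseg: int = 1000,
) -> dict[str, float]:
    """All 64 frequency-domain features of one epoch, keyed by
    :data:`FREQ_FEATURE_NAMES`."""
    spec = welch_psd(x, fs, nperseg=nperseg)
    out: dict[str, float] = {}
    for band in bands:
        out.update(band_central_tendency(spec, band))
    norm = {band.name: band_norm_power(spec, band) for band in bands}
    for band in bands:
        out[f"{band.name}_norm_power"] = norm[band.name]
    for band in bands:
        out[f"{band.name}_avg_freq"] = band_avg_frequency(spec, band)
    for band in bands:
        out[f"{band.name}_max_power"] = band_max_power(spec, band)
    out.update(band_ratios(norm))
    for i, value in enumerate(fft_top10(x)):
        out[f"fft_top{i + 1}"] = float(value)
    return out
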