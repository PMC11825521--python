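"""Seeded synthetic neonatal EEG with five-state structure.

Generates labeled multichannel recordings that carry the statistical
structure the staging pipeline assumes: 8 channels at 500 Hz, 30-s
epochs, a Markov-chain hypnogram over {W, AS1, QS1, QS2, AS2} with
imbalanced stationary distribution, and state-specific spectra — quiet
sleep dominated by slow delta (QS1 additionally alternating between
burst and inter-burst levels, QS2 continuous), active sleep broader-band,
wake with relatively more high-frequency content.

Each epoch is built as band-limited Gaussian noise per EEG band (delta,
theta, alpha, beta; filtered with the same FIR design the preprocessing
stage uses) weighted by the state's band-power profile and a per-channel
discriminability multiplier, plus a common 1/f^β background, optionally
amplitude-modulated by a burst envelope, then scaled to the state's RMS
amplitude with a lognormal per-epoch jitter. Higher ``channel_snr``
raises the state-signature power relative to the shared background, so
the channel becomes easier to classify — the knob the channel-comparison
experiments exercise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .preprocess import FilterSpec
from .recording import CODE_NAMES, DEFAULT_CHANNELS, STATE_CODES, Recording

__all__ = [
    "StateProfile",
    "SyntheticSpec",
    "default_state_profiles",
    "sample_hypnogram",
    "synthesize_epoch",
    "generate_dataset",
]

BAND_EDGES = {"delta": (0.5, 3.0), "theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}

#: RMS of the shared 1/f background relative to the unit-RMS state signature.
#: Power parity at channel_snr = 1 makes the per-channel snr multiplier the
#: dial that sets how clean the state signature is.
BACKGROUND_RMS_FRACTION = 1.0


@dataclass(frozen=True)
class StateProfile:
    """Spectral recipe for one sleep state."""

    state: str
    band_weights: dict[str, float]
    amplitude_uV: float
    burst: bool = False
    burst_period_s: float = 6.0
    burst_depth: float = 0.0
    background_exponent: float = 2.0

    def validate(self) -> None:
        if self.state not in STATE_CODES:
            raise ValueError(f"unknown state {self.state!r}")
        if set(self.band_weights) != set(BAND_EDGES):
            raise ValueError(
                f"band_weights keys must be exactly {sorted(BAND_EDGES)}"
            )
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be >= 0")
        if all(w == 0 for w in self.band_weights.values()):
            raise ValueError("at least one band weight must be positive")
        if not 0.0 <= self.burst_depth <= 1.0:
            raise ValueError("burst depth must lie in [0, 1]")
        if self.burst_period_s <= 0:
            raise ValueError("burst period must be positive")
        if self.amplitude_uV <= 0:
            raise ValueError("amplitude must be positive")


def default_state_profiles() -> dict[str, StateProfile]:
    """Qualitative five-state spectral recipes.

    These are plausible stand-ins for neonatal EEG — quiet sleep slow
    and high-amplitude, QS1 with tracé-alternant-like burst/inter-burst
    alternation, active sleep broader-band, wake with the most relative
    high-frequency power — not estimates of any clinical cohort.
    """
    return {
        "W": StateProfile(
            "W", {"delta": 1.0, "theta": 0.8, "alpha": 0.7, "beta": 0.9},
            amplitude_uV=30.0, background_exponent=2.0,
        ),
        "AS1": StateProfile(
            "AS1", {"delta": 1.5, "theta": 1.0, "alpha": 0.6, "beta": 0.5},
            amplitude_uV=32.0, background_exponent=1.9,
        ),
        "QS1": StateProfile(
            "QS1", {"delta": 3.0, "theta": 0.6, "alpha": 0.3, "beta": 0.2},
            amplitude_uV=38.0, burst=True, burst_period_s=6.0, burst_depth=0.7,
            background_exponent=2.2,
        ),
        "QS2": StateProfile(
            "QS2", {"delta": 3.5, "theta": 0.5, "alpha": 0.3, "beta": 0.15},
            amplitude_uV=40.0, background_exponent=2.3,
        ),
        "AS2": StateProfile(
            "AS2", {"delta": 2.0, "theta": 0.9, "alpha": 0.5, "beta": 0.35},
            amplitude_uV=31.0, background_exponent=2.0,
        ),
    }


def _default_class_bias() -> dict[str, float]:
    # imbalanced on purpose; the clinical class mix is unpublished
    return {"W": 0.25, "AS1": 0.25, "QS1": 0.15, "QS2": 0.15, "AS2": 0.20}


def _default_transition(class_bias: dict[str, float], dwell: float = 0.75) -> np.ndarray:
    """Sticky chain T = dwell·I + (1−dwell)·1·bias^T.

    Its stationary distribution is exactly ``class_bias``; diagonal 0.75
    gives a mean dwell of ~4 epochs (2 min runs)."""
    bias = np.array([class_bias[CODE_NAMES[c]] for c in range(1, 6)])
    return dwell * np.eye(5) + (1.0 - dwell) * np.tile(bias, (5, 1))


@dataclass
class SyntheticSpec:
    """Full recipe for a synthetic cohort."""

    n_subjects: int = 5
    epochs_per_subject: int = 120
    fs: float = 500.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    epoch_s: float = 30.0
    state_profiles: dict[str, StateProfile] = field(default_factory=default_state_profiles)
    class_bias: dict[str, float] = field(default_factory=_default_class_bias)
    transition_matrix: np.ndarray | None = None
    channel_snr: dict[str, float] = field(default_factory=dict)
    amplitude_jitter: float = 0.4  # lognormal sigma of per-epoch RMS scale
    seed: int = 0

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix = _default_transition(self.class_bias)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        for ch in self.channels:
            self.channel_snr.setdefault(ch, 1.0)

    def validate(self) -> None:
        if self.n_subjects < 1 or self.epochs_per_subject < 1:
            raise ValueError("need at least one subject and one epoch")
        spe = self.fs * self.epoch_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer")
        bias = np.array([self.class_bias[s] for s in STATE_CODES])
        if np.any(bias < 0) or abs(bias.sum() - 1) > 1e-9:
            raise ValueError("class_bias must be a probability distribution")
        t = self.transition_matrix
        if t.shape != (5, 5) or np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1) > 1e-9):
            raise ValueError("transition_matrix must be 5x5 row-stochastic")
        for profile in self.state_profiles.values():
            profile.validate()
        missing = set(STATE_CODES) - set(self.state_profiles)
        if missing:
            raise ValueError(f"missing state profiles: {sorted(missing)}")

    @property
    def bias_vector(self) -> np.ndarray:
        return np.array([self.class_bias[CODE_NAMES[c]] for c in range(1, 6)])


def sample_hypnogram(spec: SyntheticSpec, n_epochs: int, seed: int) -> np.ndarray:
    """Markov-chain hypnogram: codes 1..5, initial state drawn from
    ``class_bias``, transitions from ``transition_matrix``."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    labels = np.empty(n_epochs, dtype=int)
    labels[0] = rng.choice(5, p=spec.bias_vector) + 1
    t = spec.transition_matrix
    for i in range(1, n_epochs):
        labels[i] = rng.choice(5, p=t[labels[i - 1] - 1]) + 1
    return labels


@functools.lru_cache(maxsize=32)
def _band_taps(lo: float, hi: float, fs: float) -> np.ndarray:
    return FilterSpec(low_cut=lo, high_cut=hi).taps(fs)


def _band_noise(rng: np.random.Generator, lo: float, hi: float, fs: float, n: int) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (FIR design shared with the
    preprocessing stage; generated with padding so edges are stationary)."""
    from scipy.signal import oaconvolve

    taps = _band_taps(lo, hi, fs)
    pad = taps.size // 2
    z = rng.standard_normal(n + 2 * pad)
    y = oaconvolve(z, taps, mode="same")[pad : pad + n]
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _colored_noise(rng: np.random.Generator, beta: float, n: int) -> np.ndarray:
    """Unit-RMS 1/f^beta Gaussian noise (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    y = np.fft.irfft(spec * shape, n=n)
    return y / np.sqrt(np.mean(y**2))


#: lognormal sigma of the background's random per-epoch band mixture
BACKGROUND_BAND_SIGMA = 0.7


def _background_noise(
    rng: np.random.Generator, beta: float, fs: float, n: int
) -> np.ndarray:
    """Unit-RMS state-independent background activity.

    Half 1/f^beta colored noise, half band-limited noise with a random
    per-epoch band mixture. The random mixture is what makes the
    background a genuine confound: it perturbs exactly the band-power
    features the classifier relies on, epoch by epoch, so the
    state-signature-to-background ratio (``channel_snr``) controls how
    discriminable a channel is.
    """
    colored = _colored_noise(rng, beta, n)
    v = rng.lognormal(mean=0.0, sigma=BACKGROUND_BAND_SIGMA, size=4)
    v /= v.sum()
    mix = np.zeros(n)
    for (lo, hi), w in zip(BAND_EDGES.values(), v):
        mix += np.sqrt(w) * _band_noise(rng, lo, hi, fs, n)
    mix /= np.sqrt(np.mean(mix**2))
    y = colored + mix
    return y / np.sqrt(np.mean(y**2))


def _burst_envelope(n: int, fs: float, period_s: float, depth: float) -> np.ndarray:
    """Alternating burst / inter-burst amplitude envelope in [1-depth, 1]
    with raised-cosine ramps, starting in the burst phase."""
    t = np.arange(n) / fs
    half = period_s / 2.0
    phase = np.mod(t, period_s)
    ramp = min(0.25, period_s / 8.0)
    env = np.ones(n)
    inter = (phase >= half) & (phase < period_s)
    env[inter] = 1.0 - depth
    # smooth the two transitions per cycle
    down = (phase >= half - ramp) & (phase < half)
    env[down] = 1.0 - depth * 0.5 * (1 - np.cos(np.pi * (phase[down] - half + ramp) / ramp))
    up = phase >= period_s - ramp
    env[up] = 1.0 - depth * 0.5 * (1 + np.cos(np.pi * (phase[up] - period_s + ramp) / ramp))
    return env


def synthesize_epoch(
    profile: StateProfile,
    channel_snr: float,
    fs: float,
    epoch_s: float,
    rng: int | np.random.Generator,
    amplitude_jitter: float = 0.0,
) -> np.ndarray:
    """One single-channel epoch (µV) following a state profile.

    Band noises (power ∝ band_weights) are summed into a unit-RMS state
    signature, scaled by ``channel_snr``, mixed with the unit-RMS 1/f^β
    background at relative RMS ``BACKGROUND_RMS_FRACTION``, burst-
    modulated if the profile says so, and normalized so the epoch RMS is
    ``amplitude_uV`` (times a lognormal jitter when requested).
    """
    profile.validate()
    n = fs * epoch_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("fs * epoch_s must be an integer")
    n = int(round(n))
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    total_w = sum(profile.band_weights.values())
    signature = np.zeros(n)
    for name in ("delta", "theta", "alpha", "beta"):  # fixed RNG order
        w = profile.band_weights[name] / total_w
        if w > 0:
            lo, hi = BAND_EDGES[name]
            signature += np.sqrt(w) * _band_noise(rng, lo, hi, fs, n)
    signature /= np.sqrt(np.mean(signature**2))

    background = _background_noise(rng, profile.background_exponent, fs, n)
    y = channel_snr * signature + BACKGROUND_RMS_FRACTION * background

    if profile.burst and profile.burst_depth > 0:
        y = y * _burst_envelope(n, fs, profile.burst_period_s, profile.burst_depth)

    target = profile.amplitude_uV
    if amplitude_jitter > 0:
        target *= float(np.exp(amplitude_jitter * rng.standard_normal()))
    return y * (target / np.sqrt(np.mean(y**2)))


def generate_dataset(spec: SyntheticSpec) -> list[Recording]:
    """The full synthetic cohort: one recording per subject, each with
    its own Markov hypnogram and all configured channels. Byte-identical
    for identical (spec, seed)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    recordings = []
    spe = int(round(spec.fs * spec.epoch_s))
    for s, sseq in enumerate(subject_seeds):
        hyp_seed, noise_seq = sseq.spawn(2)
        hypnogram = sample_hypnogram(
            spec, spec.epochs_per_subject, seed=int(hyp_seed.generate_state(1)[0] % (2**31))
        )
        rng = np.random.default_rng(noise_seq)
        data = np.empty((len(spec.channels), spec.epochs_per_subject * spe))
        for e, code in enumerate(hypnogram):
            profile = spec.state_profiles[CODE_NAMES[int(code)]]
            sl = slice(e * spe, (e + 1) * spe)
            for c, ch in enumerate(spec.channels):
                data[c, sl] = synthesize_epoch(
                    profile,
                    spec.channel_snr[ch],
                    spec.fs,
                    spec.epoch_s,
                    rng,
                    amplitude_jitter=spec.amplitude_jitter,
                )
        recordings.append(
            Recording(
                data=data,
                fs=spec.fs,
                channel_names=list(spec.channels),
                subject_id=f"S{s + 1:03d}",
                hypnogram=hypnogram,
                epoch_s=spec.epoch_s,
            )
        )
    return recordings
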