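"""Shared fixtures: small synthetic cohorts, reused across test modules.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import neosleep as ns

logging.getLogger("neosleep").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def one_epoch() -> np.ndarray:
    """A single active-sleep channel-epoch (15,000 samples at 500 Hz)."""
    profile = ns.default_state_profiles()["AS1"]
    return ns.synthesize_epoch(profile, 1.0, 500, 30, rng=11)


@pytest.fixture(scope="session")
def small_recordings() -> list[ns.Recording]:
    """Two subjects x 30 epochs, two channels, C3 boosted 1.5x."""
    spec = ns.SyntheticSpec(
        n_subjects=2,
        epochs_per_subject=30,
        channels=("C3", "T4"),
        channel_snr={"C3": 1.5},
        seed=202,
    )
    return ns.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_epochs(small_recordings) -> ns.EpochSet:
    sets = [ns.segment(ns.bandpass(r)) for r in small_recordings]
    return ns.concat_epoch_sets(sets)


@pytest.fixture(scope="session")
def small_features(small_epochs) -> ns.FeatureMatrix:
    """60 labeled epochs x 188 features (C3 + T4)."""
    return ns.build_features(small_epochs)
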