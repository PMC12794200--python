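"""Shared fixtures: one small simulated subject, preprocessed once per run."""

from __future__ import annotations

import numpy as np
import pytest

from polardecode import (EncodingConfig, PreprocessConfig, ProtocolConfig,
                         build_dataset, simulate_subject)
from polardecode.pipeline import kinematics_stage, preprocess_stage


@pytest.fixture(scope="session")
def protocol_small() -> ProtocolConfig:
    return ProtocolConfig(n_sessions=2, trials_per_session=6)


@pytest.fixture(scope="session")
def encoding_default() -> EncodingConfig:
    return EncodingConfig(seed=42)


@pytest.fixture(scope="session")
def subject_trials(protocol_small, encoding_default):
    return simulate_subject(protocol_small, encoding_default)


@pytest.fixture(scope="session")
def clean_pipeline_data(subject_trials, protocol_small):
    """(angle_epochs, decode_epochs, signature_epochs, logs) for 12 trials."""
    angles = kinematics_stage(subject_trials, protocol_small)
    dec, sig, logs = preprocess_stage(subject_trials, protocol_small,
                                      PreprocessConfig())
    return angles, dec, sig, logs


@pytest.fixture(scope="session")
def tiny_dataset(clean_pipeline_data):
    angles, dec, _, _ = clean_pipeline_data
    return build_dataset(dec, angles, shuffle_seed=1, n_test=3, n_folds=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def signature_epochs():
    """Cleaned wide epochs (-1..6.5 s), 50 trials (a typical MRCP average)."""
    p = ProtocolConfig(n_sessions=5, trials_per_session=10)
    enc = EncodingConfig(seed=77)
    trials = simulate_subject(p, enc)
    _, sig, _ = preprocess_stage(trials, p, PreprocessConfig())
    arr = np.stack([e.eeg for e in sig])
    times = -1.0 + np.arange(arr.shape[-1]) / 100.0
    return arr, times


@pytest.fixture(scope="session")
def null_epochs():
    """Same pipeline with the movement-locked signatures switched off."""
    p = ProtocolConfig(n_sessions=2, trials_per_session=10)
    enc = EncodingConfig(seed=78, erd_depth=0.0, mrcp_amplitude=0.0,
                         angle_gain=0.0)
    trials = simulate_subject(p, enc)
    _, sig, _ = preprocess_stage(trials, p, PreprocessConfig())
    arr = np.stack([e.eeg for e in sig])
    times = -1.0 + np.arange(arr.shape[-1]) / 100.0
    return arr, times
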