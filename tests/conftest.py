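"""Shared fixtures: small synthetic recordings and datasets.

Everything is generated at a reduced sampling rate (500 Hz) so the whole
suite stays fast; rate-dependent arithmetic is tested explicitly at 4 kHz
where it matters.
"""

from __future__ import annotations

import numpy as np
import pytest

from silentspeech.preprocess import Annotation, Recording
from silentspeech.synthgen import (
    PhonemeSynthConfig,
    SynthConfig,
    simulate_phoneme_dataset,
    simulate_recording,
)

RATE = 500.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tongue_config():
    return SynthConfig(sampling_rate=RATE, duration=40.0,
                       event_times=(5.0, 12.0, 19.0, 26.0, 33.0), seed=7)


@pytest.fixture(scope="session")
def tongue_recording(tongue_config):
    return simulate_recording(tongue_config)


@pytest.fixture(scope="session")
def phoneme_config():
    return PhonemeSynthConfig(sampling_rate=RATE, seed=11)


@pytest.fixture(scope="session")
def phoneme_recordings(phoneme_config):
    return simulate_phoneme_dataset(phoneme_config)


@pytest.fixture(scope="session")
def tiny_phoneme_recordings():
    """2 per class per subject = 12 samples, for fast I/O and CLI tests."""
    cfg = PhonemeSynthConfig(sampling_rate=RATE, n_per_class_per_subject=2,
                             seed=3)
    return simulate_phoneme_dataset(cfg)


@pytest.fixture()
def simple_recording():
    """A deterministic two-channel recording with one annotated event."""
    rate = RATE
    t = np.arange(int(10 * rate)) / rate
    eeg = np.sin(2 * np.pi * 10.0 * t) + 0.5 * np.sin(2 * np.pi * 40.0 * t)
    emg = np.sin(2 * np.pi * 60.0 * t)
    return Recording(
        channels=np.vstack([eeg, emg]),
        channel_roles=["EEG", "EMG"],
        sampling_rate=rate,
        annotations=[Annotation(onset=5.0, duration=3.0, label="movement")],
    )
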