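import numpy as np
import pytest

from sleepdhmm.pipeline import featurize_recording
from sleepdhmm.stages import STAGES_5, default_mask
from sleepdhmm.synth import (StageSignalParams, example_transition_matrix,
                             generate_hypnogram, generate_recording,
                             synthesize_epoch)
from sleepdhmm.preprocess import EpochSignals, EPOCH_SAMPLES

FS = 256


@pytest.fixture(scope="session")
def mask():
    return default_mask()


@pytest.fixture(scope="session")
def chain(mask):
    return example_transition_matrix(mask)


@pytest.fixture(scope="session")
def default_params():
    return StageSignalParams.default()


def make_epoch(eeg=None, eog=None, emg=None) -> EpochSignals:
    """EpochSignals with zero-filled defaults for unspecified channels."""
    zeros = np.zeros(EPOCH_SAMPLES)
    return EpochSignals(
        eeg=zeros if eeg is None else np.asarray(eeg, dtype=float),
        eog=zeros if eog is None else np.asarray(eog, dtype=float),
        emg=zeros if emg is None else np.asarray(emg, dtype=float),
    )


def sine_epoch(freq_hz: float, amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(EPOCH_SAMPLES) / FS
    return amplitude * np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture(scope="session")
def stage_epochs(default_params):
    """One filtered synthetic epoch per stage (EEG/EOG/EMG conditioned)."""
    from sleepdhmm.preprocess import filter_channel
    out = {}
    for stage in STAGES_5:
        eeg, eog, emg = synthesize_epoch(stage, default_params, FS, seed=42)
        out[stage] = EpochSignals(
            eeg=filter_channel(eeg, "EEG"),
            eog=filter_channel(eog, "EOG"),
            emg=filter_channel(emg, "EMG"),
        )
    return out


@pytest.fixture(scope="session")
def small_dataset(mask, chain, default_params):
    """Six featurized subjects of 120 epochs each (shared, ~15 s to build)."""
    A, pi = chain
    subjects = []
    for s in range(6):
        hyp = generate_hypnogram(A, pi, mask, 120, seed=500 + s)
        rec = generate_recording(hyp, default_params, fs=FS, seed=900 + s,
                                 subject_id=f"subject_{s:02d}")
        feats, movement = featurize_recording(rec)
        assert not movement.any()
        subjects.append((feats, hyp))
    return subjects
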