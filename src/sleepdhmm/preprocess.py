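"""Signal conditioning: resampling, Butterworth band-pass filtering,
epoch segmentation, averaged epoch spectra, movement detection.

Fixed pipeline order: resample -> filter -> segment -> spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import gcd

import numpy as np
from scipy import signal as sps

from .synth import PSGRecording

TARGET_FS = 256
EPOCH_SAMPLES = 30 * TARGET_FS  # 7680
FFT_LEN = 512                   # 2-s windows at 256 samples/second
N_WINDOWS = 15
FREQ_RESOLUTION = TARGET_FS / FFT_LEN  # 0.5 Hz

MOVEMENT_THRESHOLD_UV = 200.0

# passbands in Hz at 256 samples/second
_BANDS = {"EEG": (0.5, 30.0), "EOG": (0.5, 30.0), "EMG": (5.0, 100.0)}
FILTER_ORDER = 8


@dataclass(frozen=True)
class EpochSignals:
    """One filtered 30-s epoch of the three channels at 256 samples/second."""

    eeg: np.ndarray
    eog: np.ndarray
    emg: np.ndarray
    epoch_index: int = 0

    def __post_init__(self) -> None:
        for name in ("eeg", "eog", "emg"):
            ch = getattr(self, name)
            if len(ch) != EPOCH_SAMPLES:
                raise ValueError(
                    f"{name} has {len(ch)} samples, expected {EPOCH_SAMPLES}")

    def channel(self, role: str) -> np.ndarray:
        try:
            return {"EEG": self.eeg, "EOG": self.eog, "EMG": self.emg}[role]
        except KeyError:
            raise ValueError(f"unknown channel role {role!r}") from None


@dataclass(frozen=True)
class EpochSpectrum:
    """Mean power spectrum of an epoch, 257 bins at 0.5 Hz resolution."""

    power: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        if len(self.power) != FFT_LEN // 2 + 1:
            raise ValueError(f"expected {FFT_LEN // 2 + 1} bins, got {len(self.power)}")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("non-finite power values")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(len(self.power)) * FREQ_RESOLUTION


def resample_to_256(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Polyphase-resample to 256 samples/second (identity at 256)."""
    fs_in = float(fs_in)
    if fs_in < TARGET_FS:
        raise ValueError(f"fs_in={fs_in:g} < {TARGET_FS}: upsampling unsupported")
    if fs_in == TARGET_FS:
        return np.asarray(x, dtype=float)
    if not fs_in.is_integer():
        raise ValueError("non-integer input sampling rates are unsupported")
    g = gcd(TARGET_FS, int(fs_in))
    up, down = TARGET_FS // g, int(fs_in) // g
    return sps.resample_poly(np.asarray(x, dtype=float), up, down)


@lru_cache(maxsize=None)
def _sos(role: str):
    try:
        lo, hi = _BANDS[role]
    except KeyError:
        raise ValueError(f"unknown channel role {role!r}") from None
    hi = min(hi, 0.99 * TARGET_FS / 2)
    return sps.butter(FILTER_ORDER, [lo, hi], btype="bandpass",
                      fs=TARGET_FS, output="sos")


def filter_channel(x: np.ndarray, role: str, zero_phase: bool = False) -> np.ndarray:
    """Order-8 Butterworth band-pass (0.5-30 Hz EEG/EOG, 5-100 Hz EMG).

    Causal by default, matching an online-capable system; ``zero_phase``
    applies the filter forward and backward instead.
    """
    sos = _sos(role)
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return x
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def preprocess_recording(recording: PSGRecording,
                         zero_phase: bool = False) -> PSGRecording:
    """Resample to 256 samples/second and band-pass each channel."""
    chans = {}
    for role, attr in (("EEG", "eeg"), ("EOG", "eog"), ("EMG", "emg")):
        x = resample_to_256(getattr(recording, attr), recording.fs)
        chans[attr] = filter_channel(x, role, zero_phase=zero_phase)
    return PSGRecording(fs=TARGET_FS, subject_id=recording.subject_id, **chans)


def segment_epochs(recording: PSGRecording) -> list[EpochSignals]:
    """Split into 30-s epochs; a trailing partial epoch is discarded."""
    if recording.fs != TARGET_FS:
        raise ValueError(f"expected {TARGET_FS} samples/second, got {recording.fs:g}")
    n_epochs = recording.n_samples // EPOCH_SAMPLES
    out = []
    for k in range(n_epochs):
        sl = slice(k * EPOCH_SAMPLES, (k + 1) * EPOCH_SAMPLES)
        out.append(EpochSignals(eeg=recording.eeg[sl], eog=recording.eog[sl],
                                emg=recording.emg[sl], epoch_index=k))
    return out


def epoch_spectrum(epoch: EpochSignals, channel: str) -> EpochSpectrum:
    """Average the power spectra of the fifteen non-overlapping 2-s windows.

    Rectangular window, 512-point FFT; power is |X|^2 / N on a linear
    scale (ratio and mean-frequency features are scale-sensitive, so the
    dB view is reserved for reporting).
    """
    x = epoch.channel(channel)
    windows = x.reshape(N_WINDOWS, FFT_LEN)
    spectra = np.abs(np.fft.rfft(windows, axis=1)) ** 2 / FFT_LEN
    return EpochSpectrum(power=spectra.mean(axis=0), channel=channel)


def detect_movement(epoch: EpochSignals) -> bool:
    """True iff the EEG exceeds 200 μV in absolute amplitude (strict)."""
    return bool(np.max(np.abs(epoch.eeg)) > MOVEMENT_THRESHOLD_UV)
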