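"""The 13 per-epoch features: total powers, band power ratios, mean
spectral frequencies, the three duration ratios, and EMG mean amplitude.

Band/bin convention: a band [lo, hi] collects spectrum bins whose center
frequency f satisfies lo <= f < hi, except that the 30 Hz edge is
inclusive (so the full 0-30 band ratio is exactly 1 and the four EEG
bands tile 0-30 up to the deliberate 13-22 Hz gap).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .preprocess import (EPOCH_SAMPLES, FFT_LEN, FREQ_RESOLUTION, TARGET_FS,
                         EpochSignals, EpochSpectrum, epoch_spectrum)

FEATURE_NAMES = (
    "eeg_total_power",
    "emg_total_power",
    "eeg_pr_0_4",
    "eeg_pr_4_8",
    "eeg_pr_8_13",
    "eeg_pr_22_30",
    "eog_pr_0_4",
    "eeg_sf",
    "emg_sf",
    "alpha_ratio",
    "spindle_ratio",
    "sws_ratio",
    "emg_mean_amplitude",
)
N_FEATURES = 13

WINDOW_SECONDS = 1          # duration-ratio analysis window
WINDOW_SAMPLES = TARGET_FS * WINDOW_SECONDS
N_RATIO_WINDOWS = EPOCH_SAMPLES // WINDOW_SAMPLES  # 30

ALPHA_RMS_THRESHOLD = 0.5
SIGMA_POWER_THRESHOLD = 0.5
SPINDLE_PEAK_FACTOR = 2.0   # "sudden amplitude change": peak > 2x median window peak
SWS_AMPLITUDE_UV = 75.0


@dataclass(frozen=True)
class FeatureVector:
    """The 13 features of one epoch, in fixed order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")

    def __getitem__(self, key: str | int) -> float:
        if isinstance(key, str):
            key = FEATURE_NAMES.index(key)
        return float(self.values[key])


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    m = (freqs >= lo) & (freqs < hi)
    if hi == 30.0:
        m |= freqs == hi
    return m


def total_power(spectrum: EpochSpectrum) -> float:
    """Sum of spectral power over 0-30 Hz inclusive."""
    f = spectrum.freqs
    return float(spectrum.power[(f >= 0.0) & (f <= 30.0)].sum())


def power_ratio(spectrum: EpochSpectrum, band_low: float, band_high: float) -> float:
    """Band power over total 0-30 Hz power; 0 when the total is 0."""
    if not (0.0 <= band_low < band_high <= 30.0):
        raise ValueError(f"invalid band [{band_low}, {band_high}]")
    tot = total_power(spectrum)
    if tot == 0.0:
        return 0.0
    band = spectrum.power[_band_mask(spectrum.freqs, band_low, band_high)].sum()
    return float(band / tot)


def spectral_frequency(spectrum: EpochSpectrum) -> float:
    """Power-weighted mean frequency over 0-30 Hz; 0 when total power is 0."""
    f = spectrum.freqs
    sel = (f >= 0.0) & (f <= 30.0)
    p = spectrum.power[sel]
    tot = p.sum()
    if tot == 0.0:
        return 0.0
    return float((f[sel] * p).sum() / tot)


@lru_cache(maxsize=None)
def _band_sos(lo: float, hi: float, order: int):
    return sps.butter(order, [lo, hi], btype="bandpass", fs=TARGET_FS, output="sos")


def _bandpass(x: np.ndarray, lo: float, hi: float, order: int = 8) -> np.ndarray:
    # zero-phase here: window-level amplitude tests should not be skewed
    # by filter delay
    return sps.sosfiltfilt(_band_sos(lo, hi, order), x)


def _window_rms(x: np.ndarray) -> np.ndarray:
    w = x[: N_RATIO_WINDOWS * WINDOW_SAMPLES].reshape(N_RATIO_WINDOWS, WINDOW_SAMPLES)
    return np.sqrt((w ** 2).mean(axis=1))


def _window_peak(x: np.ndarray) -> np.ndarray:
    w = x[: N_RATIO_WINDOWS * WINDOW_SAMPLES].reshape(N_RATIO_WINDOWS, WINDOW_SAMPLES)
    return np.abs(w).max(axis=1)


def alpha_ratio(epoch: EpochSignals) -> float:
    """Fraction of 1-s windows dominated by alpha/beta activity.

    The 8-13 Hz and 22-30 Hz filtered signals are summed; a window is an
    alpha window when the combined RMS exceeds half the broadband RMS.
    """
    eeg = epoch.eeg
    combined = _bandpass(eeg, 8.0, 13.0) + _bandpass(eeg, 22.0, 30.0)
    rms_c = _window_rms(combined)
    rms_b = _window_rms(eeg)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rms_b > 0, rms_c / np.where(rms_b > 0, rms_b, 1.0), 0.0)
    return float((frac > ALPHA_RMS_THRESHOLD).mean())


def spindle_ratio(epoch: EpochSignals) -> float:
    """Fraction of 1-s windows that look like sleep spindles.

    A spindle window needs (a) sigma-band 12-15 Hz power above half of
    that window's 0-30 Hz power and (b) a sudden amplitude change: the
    window's peak sigma-filtered amplitude above twice the epoch-median
    window peak.
    """
    eeg = epoch.eeg
    w = eeg[: N_RATIO_WINDOWS * WINDOW_SAMPLES].reshape(N_RATIO_WINDOWS, WINDOW_SAMPLES)
    spec = np.abs(np.fft.rfft(w, axis=1)) ** 2
    freqs = np.fft.rfftfreq(WINDOW_SAMPLES, 1.0 / TARGET_FS)
    sigma = spec[:, (freqs >= 12.0) & (freqs <= 15.0)].sum(axis=1)
    total = spec[:, (freqs >= 0.0) & (freqs <= 30.0)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_frac = np.where(total > 0, sigma / np.where(total > 0, total, 1.0), 0.0)

    peaks = _window_peak(_bandpass(eeg, 12.0, 15.0))
    median_peak = np.median(peaks)
    sudden = peaks > SPINDLE_PEAK_FACTOR * median_peak

    return float(((sigma_frac > SIGMA_POWER_THRESHOLD) & sudden).mean())


def sws_ratio(epoch: EpochSignals) -> float:
    """Fraction of 1-s windows with 0.5-2 Hz activity above 75 μV peak."""
    slow = _bandpass(epoch.eeg, 0.5, 2.0, order=3)
    return float((_window_peak(slow) > SWS_AMPLITUDE_UV).mean())


def emg_energy(epoch: EpochSignals) -> float:
    """Mean absolute EMG amplitude over the whole epoch."""
    return float(np.abs(epoch.emg).mean())


def extract_features(epoch: EpochSignals) -> FeatureVector:
    """All 13 features of one filtered epoch, in fixed order."""
    for role, attr in (("EEG", "eeg"), ("EOG", "eog"), ("EMG", "emg")):
        if getattr(epoch, attr, None) is None:
            raise ValueError(f"missing channel {role}")
    eeg_spec = epoch_spectrum(epoch, "EEG")
    eog_spec = epoch_spectrum(epoch, "EOG")
    emg_spec = epoch_spectrum(epoch, "EMG")
    values = np.array([
        total_power(eeg_spec),
        total_power(emg_spec),
        power_ratio(eeg_spec, 0.0, 4.0),
        power_ratio(eeg_spec, 4.0, 8.0),
        power_ratio(eeg_spec, 8.0, 13.0),
        power_ratio(eeg_spec, 22.0, 30.0),
        power_ratio(eog_spec, 0.0, 4.0),
        spectral_frequency(eeg_spec),
        spectral_frequency(emg_spec),
        alpha_ratio(epoch),
        spindle_ratio(epoch),
        sws_ratio(epoch),
        emg_energy(epoch),
    ])
    return FeatureVector(values=values)


def feature_matrix(epochs: list[EpochSignals]) -> np.ndarray:
    """Stack per-epoch feature vectors into an (n_epochs, 13) array."""
    if not epochs:
        return np.empty((0, N_FEATURES))
    return np.vstack([extract_features(e).values for e in epochs])


def write_features_tsv(matrix: np.ndarray, path: str | Path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write("epoch_index\t" + "\t".join(FEATURE_NAMES) + "\n")
        for i, row in enumerate(matrix):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_features_tsv(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["epoch_index", *FEATURE_NAMES]:
            raise ValueError(f"{path}: unexpected feature columns")
        body = fh.read()
    if not body.strip():
        return np.empty((0, N_FEATURES))
    data = np.loadtxt(body.splitlines(), delimiter="\t", ndmin=2)
    return data[:, 1:]
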