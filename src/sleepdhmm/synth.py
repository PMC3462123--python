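"""Synthetic stage-labeled PSG generation.

Produces 30-s EEG/EOG/EMG epochs whose band content follows the visual
scoring criteria for each stage (alpha-dominant Wake, theta S1, spindle
bursts in S2, high-voltage slow waves in SWS, low-voltage mixed REM with
atonia), and whole-night recordings driven by an allowed-transition
Markov chain. This stands in for clinical recordings in every test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .stages import EPOCH_SECONDS, STAGES_5, STAGES_6, Hypnogram, TransitionMask, default_mask

DEFAULT_FS = 256.0


@dataclass(frozen=True)
class StageParams:
    """Band amplitudes (μV) and event rates for one stage's signal model."""

    delta: float = 0.0       # 0.5-2 Hz
    theta: float = 0.0       # 4-8 Hz (low-voltage mixed 3-7 Hz activity)
    alpha: float = 0.0       # 8-13 Hz
    beta: float = 0.0        # 22-30 Hz
    spindle_amp: float = 0.0     # 12-15 Hz sigma burst amplitude
    spindle_rate: float = 0.0    # bursts per 30-s epoch
    eog_slow_amp: float = 0.0    # slow rolling eye movements, ~0.3 Hz
    eog_rapid_amp: float = 0.0   # rapid eye movements, ~1.5-3 Hz
    emg_level: float = 0.0       # tonic chin EMG, Gaussian sigma in μV
    noise_sd: float = 0.0        # broadband additive noise, all channels

    def __post_init__(self) -> None:
        for name in ("delta", "theta", "alpha", "beta", "spindle_amp",
                     "spindle_rate", "eog_slow_amp", "eog_rapid_amp",
                     "emg_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class StageSignalParams:
    """Per-stage signal models; defaults chosen for stage separability."""

    per_stage: Mapping[str, StageParams]

    def __getitem__(self, stage: str) -> StageParams:
        try:
            return self.per_stage[stage]
        except KeyError:
            raise ValueError(f"unknown stage label {stage!r}") from None

    @classmethod
    def default(cls) -> "StageSignalParams":
        return cls(per_stage={
            "Wake": StageParams(delta=5, theta=5, alpha=45, beta=12,
                                eog_slow_amp=5, emg_level=20, noise_sd=3),
            "S1": StageParams(delta=8, theta=30, alpha=6, beta=3,
                              eog_slow_amp=40, emg_level=10, noise_sd=3),
            "S2": StageParams(delta=15, theta=25, alpha=5, beta=3,
                              spindle_amp=50, spindle_rate=3,
                              eog_slow_amp=5, emg_level=8, noise_sd=3),
            # delta amplitude 120 μV keeps >50% of the epoch above the
            # 75 μV slow-wave threshold by construction
            "SWS": StageParams(delta=120, theta=10, alpha=3, beta=2,
                               eog_slow_amp=3, emg_level=5, noise_sd=3),
            "REM": StageParams(delta=8, theta=20, alpha=5, beta=4,
                               eog_rapid_amp=60, emg_level=2, noise_sd=3),
            "Mov": StageParams(delta=80, theta=280, alpha=40, beta=40,
                               eog_slow_amp=20, emg_level=60, noise_sd=10),
        })

    @classmethod
    def silent(cls) -> "StageSignalParams":
        """All amplitudes and noise zero; every channel is identically 0."""
        return cls(per_stage={s: StageParams() for s in STAGES_6})


@dataclass(frozen=True)
class PSGRecording:
    """Three-channel sampled PSG in μV."""

    eeg: np.ndarray
    eog: np.ndarray
    emg: np.ndarray
    fs: float
    subject_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (len(self.eeg) == len(self.eog) == len(self.emg)):
            raise ValueError("channel lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, role: str) -> np.ndarray:
        try:
            return {"EEG": self.eeg, "EOG": self.eog, "EMG": self.emg}[role]
        except KeyError:
            raise ValueError(f"unknown channel role {role!r}") from None


def generate_hypnogram(A_true: np.ndarray, pi_true: np.ndarray,
                       mask: TransitionMask, n_epochs: int,
                       seed: int) -> Hypnogram:
    """Sample a stage sequence from a masked Markov chain.

    Rejects transition matrices that put probability on a masked cell,
    naming the offending stage pair.
    """
    A = np.asarray(A_true, dtype=float)
    pi = np.asarray(pi_true, dtype=float)
    n = mask.n_states
    if A.shape != (n, n):
        raise ValueError(f"A shape {A.shape} does not match {n} states")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("rows of A_true must sum to 1")
    if not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi_true must sum to 1")
    bad = (A > 0) & ~mask.allowed
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            "A_true assigns probability to masked transition "
            f"{mask.state_names[i]}->{mask.state_names[j]}"
        )
    if n_epochs == 0:
        return Hypnogram(stages=())
    rng = np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = rng.choice(n, p=pi)
    for t in range(1, n_epochs):
        states[t] = rng.choice(n, p=A[states[t - 1]])
    return Hypnogram.from_indices(states, mask.state_names)


def _tone(rng: np.random.Generator, t: np.ndarray, amp: float,
          f_lo: float, f_hi: float) -> np.ndarray:
    """One sinusoid with frequency drawn inside the band, random phase."""
    if amp == 0:
        return np.zeros_like(t)
    f = rng.uniform(f_lo, f_hi)
    phase = rng.uniform(0, 2 * np.pi)
    return amp * np.sin(2 * np.pi * f * t + phase)


def synthesize_epoch(stage: str, params: StageSignalParams, fs: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One 30-s (eeg, eog, emg) segment for a stage; deterministic per seed."""
    if fs < 200:
        raise ValueError("fs must be >= 200 samples/second")
    p = params[stage]
    rng = np.random.default_rng(seed)
    n = int(round(EPOCH_SECONDS * fs))
    t = np.arange(n) / fs

    eeg = (_tone(rng, t, p.delta, 0.75, 1.5)
           + _tone(rng, t, p.theta, 4.0, 7.0)
           + _tone(rng, t, p.alpha, 8.5, 12.5)
           + _tone(rng, t, p.beta, 22.5, 29.0))

    # sleep spindles: amplitude-modulated sigma tones, 0.5-1.5 s long,
    # onsets uniform within the epoch
    if p.spindle_rate > 0 and p.spindle_amp > 0:
        n_bursts = rng.poisson(p.spindle_rate)
        for _ in range(n_bursts):
            dur = rng.uniform(0.5, 1.5)
            onset = rng.uniform(0, EPOCH_SECONDS - dur)
            i0, i1 = int(onset * fs), int((onset + dur) * fs)
            envelope = np.hanning(i1 - i0)
            phase = rng.uniform(0, 2 * np.pi)
            burst = envelope * np.sin(2 * np.pi * 13.5 * t[i0:i1] + phase)
            eeg[i0:i1] += p.spindle_amp * burst

    eog = (_tone(rng, t, p.eog_slow_amp, 0.25, 0.45)
           + _tone(rng, t, p.eog_rapid_amp, 1.5, 3.0))

    emg = p.emg_level * rng.standard_normal(n) if p.emg_level > 0 else np.zeros(n)

    # raised-cosine taper at both ends removes the phase discontinuity
    # between concatenated epochs, which would otherwise ring through the
    # sharp 0.5 Hz high-pass edge and trip the 200 μV movement rule
    ramp_n = int(0.25 * fs)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        for ch in (eeg, eog):
            ch[:ramp_n] *= ramp
            ch[-ramp_n:] *= ramp[::-1]

    if p.noise_sd > 0:
        eeg = eeg + p.noise_sd * rng.standard_normal(n)
        eog = eog + p.noise_sd * rng.standard_normal(n)
        emg = emg + p.noise_sd * rng.standard_normal(n)
    return eeg, eog, emg


def generate_recording(hypnogram: Hypnogram, params: StageSignalParams,
                       fs: float = DEFAULT_FS, seed: int = 0,
                       subject_id: str = "synthetic") -> PSGRecording:
    """Concatenate per-epoch segments for a whole hypnogram."""
    if len(hypnogram) == 0:
        raise ValueError("hypnogram must be nonempty")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(hypnogram))
    chunks = [synthesize_epoch(stage, params, fs, int(s))
              for stage, s in zip(hypnogram, child_seeds)]
    eeg = np.concatenate([c[0] for c in chunks])
    eog = np.concatenate([c[1] for c in chunks])
    emg = np.concatenate([c[2] for c in chunks])
    return PSGRecording(eeg=eeg, eog=eog, emg=emg, fs=fs, subject_id=subject_id)


def example_transition_matrix(mask: TransitionMask | None = None) -> tuple[np.ndarray, np.ndarray]:
    """A plausible healthy-night (A, pi) consistent with the default mask."""
    mask = mask or default_mask()
    names = list(mask.state_names)
    base = {
        "Wake": {"Wake": 0.88, "S1": 0.12},
        "S1":   {"Wake": 0.05, "S1": 0.55, "S2": 0.32, "REM": 0.08},
        "S2":   {"Wake": 0.02, "S1": 0.04, "S2": 0.78, "SWS": 0.10, "REM": 0.06},
        "SWS":  {"S2": 0.12, "SWS": 0.88},
        "REM":  {"Wake": 0.03, "S1": 0.05, "S2": 0.08, "REM": 0.84},
        "Mov":  {},
    }
    n = mask.n_states
    A = np.zeros((n, n))
    for i, src in enumerate(names):
        row = base.get(src, {})
        for dst, p in row.items():
            if dst in names:
                A[i, names.index(dst)] = p
        missing = 1.0 - A[i].sum()
        if missing > 1e-12:
            # spread the remainder over allowed cells (covers Mov mode)
            extra = mask.allowed[i] & (A[i] == 0)
            if extra.any():
                A[i, extra] += missing / extra.sum()
            else:
                A[i, i] += missing
    A /= A.sum(axis=1, keepdims=True)
    pi = np.zeros(n)
    pi[names.index("Wake")] = 0.9
    pi[names.index("S1")] = 0.1
    return A, pi


def balanced_transition_matrix(mask: TransitionMask, self_weight: float = 3.0,
                               n_iter: int = 2000) -> np.ndarray:
    """Sinkhorn-balance the mask into a near doubly stochastic matrix.

    Doubly stochastic chains have uniform stationary distribution, which
    gives every state equal visitation in parameter-recovery tests.
    """
    W = mask.allowed.astype(float)
    W[np.diag_indices_from(W)] *= self_weight
    for _ in range(n_iter):
        W /= W.sum(axis=1, keepdims=True)
        W /= W.sum(axis=0, keepdims=True)
    W /= W.sum(axis=1, keepdims=True)
    return W


def write_signals_txt(recording: PSGRecording, path: str | Path) -> None:
    """Delimited text: header line with fs, then one column per channel."""
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs:g}\n")
        fh.write("eeg\teog\temg\n")
        for a, b, c in zip(recording.eeg, recording.eog, recording.emg):
            fh.write(f"{a:.6f}\t{b:.6f}\t{c:.6f}\n")


def read_signals_txt(path: str | Path, subject_id: str | None = None) -> PSGRecording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header")
        fs = float(header.split("=", 1)[1])
        cols = fh.readline().strip().split("\t")
        if cols != ["eeg", "eog", "emg"]:
            raise ValueError(f"{path}: expected columns eeg/eog/emg, got {cols}")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.size == 0:
        data = data.reshape(0, 3)
    return PSGRecording(eeg=data[:, 0], eog=data[:, 1], emg=data[:, 2],
                        fs=fs, subject_id=subject_id or Path(path).stem)
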