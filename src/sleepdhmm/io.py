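"""File formats: a minimal EDF codec plus helpers shared by the CLI.

The EDF implementation covers exactly what the pipeline needs — equal
sampling rate continuous signals, one data record per second, physical
units in μV — and round-trips through the standard 16-bit integer
encoding.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .synth import PSGRecording

_CHANNELS = (("EEG C3-A2", "eeg"), ("EOG", "eog"), ("EMG chin", "emg"))


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: PSGRecording, path: str | Path) -> None:
    """Write the three channels as an EDF file, one data record per second."""
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF export needs an integer sampling rate")
    fs = int(fs)
    n_records = recording.n_samples // fs
    if n_records * fs != recording.n_samples:
        raise ValueError("recording length must be a whole number of seconds")
    ns = len(_CHANNELS)

    signals = [np.asarray(getattr(recording, attr), dtype=float)
               for _, attr in _CHANNELS]
    phys = []
    digitized = []
    for x in signals:
        lo, hi = float(x.min(initial=0.0)), float(x.max(initial=0.0))
        if hi <= lo:
            hi = lo + 1.0
        phys.append((lo, hi))
        scale = (hi - lo) / 65535.0
        d = np.round((x - lo) / scale) - 32768
        digitized.append(d.astype("<i2"))

    header = b""
    header += _field("0", 8)
    header += _field(recording.subject_id, 80)
    header += _field("synthetic PSG", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (ns + 1)), 8)
    header += _field("", 44)
    header += _field(str(n_records), 8)
    header += _field("1", 8)
    header += _field(str(ns), 4)

    labels, transducers, dims, pmins, pmaxs, dmins, dmaxs, prefilters, sprs, reserved = (
        [] for _ in range(10))
    for (label, _), (lo, hi) in zip(_CHANNELS, phys):
        labels.append(_field(label, 16))
        transducers.append(_field("", 80))
        dims.append(_field("uV", 8))
        pmins.append(_field(f"{lo:.8g}"[:8], 8))
        pmaxs.append(_field(f"{hi:.8g}"[:8], 8))
        dmins.append(_field("-32768", 8))
        dmaxs.append(_field("32767", 8))
        prefilters.append(_field("", 80))
        sprs.append(_field(str(fs), 8))
        reserved.append(_field("", 32))
    for group in (labels, transducers, dims, pmins, pmaxs, dmins, dmaxs,
                  prefilters, sprs, reserved):
        header += b"".join(group)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digitized:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())


def read_edf(path: str | Path,
             channel_map: dict[str, str] | None = None) -> PSGRecording:
    """Read an EDF file into a PSGRecording.

    ``channel_map`` maps signal labels to roles (EEG/EOG/EMG); by
    default any label containing the role name is accepted.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")

    def f(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", "replace").strip()

    subject_id = f(8, 80)
    header_bytes = int(f(184, 8))
    n_records = int(f(236, 8))
    record_duration = float(f(244, 8))
    ns = int(f(252, 4))

    def sig_fields(base: int, width: int) -> list[str]:
        out = []
        for s in range(ns):
            off = 256 + base * ns + s * width
            out.append(raw[off:off + width].decode("ascii", "replace").strip())
        return out

    # per-signal field blocks appear in fixed order after the main header
    off = 0
    labels = sig_fields(off, 16); off += 16
    off += 80  # transducer
    off += 8   # physical dimension
    pmins = [float(v) for v in sig_fields(off, 8)]; off += 8
    pmaxs = [float(v) for v in sig_fields(off, 8)]; off += 8
    dmins = [int(v) for v in sig_fields(off, 8)]; off += 8
    dmaxs = [int(v) for v in sig_fields(off, 8)]; off += 8
    off += 80  # prefiltering
    sprs = [int(v) for v in sig_fields(off, 8)]

    data = np.frombuffer(raw[header_bytes:], dtype="<i2")
    rec_len = sum(sprs)
    if len(data) < n_records * rec_len:
        raise ValueError(f"{path}: EDF data shorter than header promises")
    data = data[: n_records * rec_len].reshape(n_records, rec_len)

    signals = {}
    fs = None
    start = 0
    for s, label in enumerate(labels):
        chunk = data[:, start:start + sprs[s]].reshape(-1).astype(float)
        start += sprs[s]
        scale = (pmaxs[s] - pmins[s]) / (dmaxs[s] - dmins[s])
        physical = pmins[s] + (chunk - dmins[s]) * scale
        if channel_map and label in channel_map:
            role = channel_map[label]
        else:
            role = next((r for r in ("EEG", "EOG", "EMG") if r in label.upper()), None)
        if role is None:
            continue
        signals[role.lower()] = physical
        fs = sprs[s] / record_duration
    missing = {"eeg", "eog", "emg"} - set(signals)
    if missing:
        raise ValueError(f"{path}: could not resolve channel roles {sorted(missing)}")
    return PSGRecording(fs=float(fs), subject_id=subject_id or Path(path).stem,
                        **signals)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
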