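"""Sleep stage labels, hypnograms, and the allowed-transition mask.

Stage order is fixed as Wake, S1, S2, SWS, REM (and Mov when the
six-state mode is enabled) so that index pair (0, 3) always refers to
the Wake-to-SWS transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

STAGES_5 = ("Wake", "S1", "S2", "SWS", "REM")
STAGES_6 = STAGES_5 + ("Mov",)

EPOCH_SECONDS = 30.0


def stage_index(label: str, state_names: Sequence[str] = STAGES_5) -> int:
    """Map a stage label to its fixed integer index."""
    try:
        return state_names.index(label) if isinstance(state_names, list) else list(state_names).index(label)
    except ValueError:
        raise ValueError(f"unknown stage label {label!r}; expected one of {tuple(state_names)}") from None


@dataclass(frozen=True)
class Hypnogram:
    """Ordered stage labels, one per 30-s epoch."""

    stages: tuple[str, ...]
    epoch_duration_s: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        allowed = set(STAGES_6)
        for s in self.stages:
            if s not in allowed:
                raise ValueError(f"unknown stage label {s!r}")

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    def __getitem__(self, i):
        return self.stages[i]

    def indices(self, state_names: Sequence[str] = STAGES_5) -> np.ndarray:
        """Integer-coded stages in the fixed state order."""
        names = list(state_names)
        return np.array([names.index(s) for s in self.stages], dtype=np.int64)

    @classmethod
    def from_indices(cls, idx: Iterable[int], state_names: Sequence[str] = STAGES_5) -> "Hypnogram":
        names = list(state_names)
        return cls(stages=tuple(names[int(i)] for i in idx))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch_index\tstage\n")
            for i, s in enumerate(self.stages):
                fh.write(f"{i}\t{s}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Hypnogram":
        stages = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("epoch_index"):
                raise ValueError(f"{path}: expected 'epoch_index<TAB>stage' header")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                _, stage = line.split("\t")
                stages.append(stage)
        return cls(stages=tuple(stages))


@dataclass(frozen=True)
class TransitionMask:
    """Boolean matrix of allowed stage-to-stage transitions.

    ``allowed[i, j]`` is True when a step from state i to state j may
    occur. Every state must allow its own self-transition.
    """

    allowed: np.ndarray
    state_names: tuple[str, ...] = STAGES_5

    def __post_init__(self) -> None:
        allowed = np.asarray(self.allowed, dtype=bool)
        object.__setattr__(self, "allowed", allowed)
        n = len(self.state_names)
        if allowed.shape != (n, n):
            raise ValueError(f"mask shape {allowed.shape} does not match {n} states")
        if not np.all(np.diag(allowed)):
            raise ValueError("all self-transitions must be allowed")
        if not np.all(allowed.any(axis=1)):
            raise ValueError("every state needs at least one allowed outgoing transition")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def validate_sequence(self, hypnogram: Hypnogram) -> None:
        """Raise if any consecutive pair in the hypnogram is disallowed."""
        idx = hypnogram.indices(self.state_names)
        for t in range(len(idx) - 1):
            if not self.allowed[idx[t], idx[t + 1]]:
                a, b = self.state_names[idx[t]], self.state_names[idx[t + 1]]
                raise ValueError(f"disallowed transition {a}->{b} at epoch {t}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_names": list(self.state_names),
            "allowed": self.allowed.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionMask":
        payload = json.loads(Path(path).read_text())
        return cls(
            allowed=np.array(payload["allowed"], dtype=bool),
            state_names=tuple(payload["state_names"]),
        )


def default_mask(include_mov: bool = False) -> TransitionMask:
    """The default allowed-transition diagram for healthy sleep.

    Loaded from the packaged ``data/default_mask.json`` config so the
    generator and the decoder share one editable source of truth.
    Wake->SWS and SWS->Wake are disallowed; SWS is reachable only
    through S2.
    """
    ref = resources.files("sleepdhmm.data").joinpath("default_mask.json")
    payload = json.loads(ref.read_text())
    names = tuple(payload["state_names"])
    allowed = np.array(payload["allowed"], dtype=bool)
    if include_mov:
        n = len(names) + 1
        full = np.zeros((n, n), dtype=bool)
        full[: n - 1, : n - 1] = allowed
        # movement epochs may interrupt and resume any stage
        full[n - 1, :] = True
        full[:, n - 1] = True
        return TransitionMask(allowed=full, state_names=names + ("Mov",))
    return TransitionMask(allowed=allowed, state_names=names)
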