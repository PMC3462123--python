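"""Declarative pipeline configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .stages import TransitionMask, default_mask


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with the experiment defaults."""

    m: int = 50                      # codebook size (30/40/50/60 were explored)
    epoch_seconds: float = 30.0
    target_fs: int = 256
    ratio_window_seconds: float = 1.0
    smoothing: float = 1.0           # emission pseudo-count
    seed: int = 0
    mask_file: str | None = None     # None -> packaged default mask
    zero_phase: bool = False         # channel filters causal by default
    exclude_movement: bool = True    # drop >200 μV epochs from agreement

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("codebook size m must be a positive integer")
        if self.smoothing < 0:
            raise ValueError("smoothing must be nonnegative")

    def mask(self) -> TransitionMask:
        if self.mask_file:
            return TransitionMask.from_json(self.mask_file)
        return default_mask()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))
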