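"""Agreement scoring between reference and automatic hypnograms, plus
the repeated 2-fold cross-validation protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .stages import STAGES_5, Hypnogram, TransitionMask

KAPPA_BINS = (
    (0.00, "poor"),        # < 0.00
    (0.20, "slight"),      # 0.00 - 0.20
    (0.40, "fair"),        # 0.21 - 0.40
    (0.60, "moderate"),    # 0.41 - 0.60
    (0.80, "substantial"), # 0.61 - 0.80
)                          # > 0.80 -> excellent


@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows are reference (manual) stages, columns predicted stages."""

    counts: np.ndarray
    state_names: tuple[str, ...] = STAGES_5

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        n = len(self.state_names)
        if c.shape != (n, n):
            raise ValueError(f"counts shape {c.shape} != ({n}, {n})")
        if np.any(c < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Per-reference-stage row percentages (NaN for absent stages)."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, 100.0 * self.counts / rows, np.nan)


@dataclass(frozen=True)
class AgreementReport:
    per_stage_sensitivity: tuple[float, ...]  # %, NaN for absent stages
    m_ssrr: float                             # %
    kappa: float
    kappa_band: str
    n_epochs: int
    state_names: tuple[str, ...] = STAGES_5

    def to_dict(self) -> dict:
        return {
            "per_stage_sensitivity": {
                s: (None if np.isnan(v) else v)
                for s, v in zip(self.state_names, self.per_stage_sensitivity)
            },
            "m_ssrr": self.m_ssrr,
            "kappa": self.kappa,
            "kappa_band": self.kappa_band,
            "n_epochs": self.n_epochs,
        }


def confusion(reference: Hypnogram, predicted: Hypnogram,
              state_names: Sequence[str] = STAGES_5) -> ConfusionMatrix:
    """Tally (reference, predicted) stage pairs epoch by epoch."""
    if len(reference) != len(predicted):
        raise ValueError(
            f"length mismatch: reference {len(reference)} vs predicted {len(predicted)}")
    names = tuple(state_names)
    n = len(names)
    counts = np.zeros((n, n), dtype=np.int64)
    r = reference.indices(names)
    p = predicted.indices(names)
    np.add.at(counts, (r, p), 1)
    return ConfusionMatrix(counts=counts, state_names=names)


def m_ssrr(cm: ConfusionMatrix) -> float:
    """Overall recognition rate: 100 x (diagonal sum / total epochs)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement K = (Po - Pe) / (1 - Pe)."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / total
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    pe = float((rows * cols).sum()) / total ** 2
    if pe >= 1.0:
        raise ValueError("chance agreement Pe = 1 (single category); kappa undefined")
    return (po - pe) / (1.0 - pe)


def interpret_kappa(k: float) -> str:
    """Landis-Koch agreement category for a kappa value."""
    if k > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if k < 0.0:
        return "poor"
    for upper, name in KAPPA_BINS[1:]:
        if k <= upper:
            return name
    return "excellent"


def per_stage_sensitivity(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal row percentages; NaN where the reference stage is absent."""
    rows = cm.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(rows > 0, 100.0 * np.diag(cm.counts) / rows, np.nan)


def agreement_report(cm: ConfusionMatrix) -> AgreementReport:
    k = cohen_kappa(cm)
    return AgreementReport(
        per_stage_sensitivity=tuple(per_stage_sensitivity(cm)),
        m_ssrr=m_ssrr(cm),
        kappa=k,
        kappa_band=interpret_kappa(k),
        n_epochs=cm.total,
        state_names=cm.state_names,
    )


def format_report(cm: ConfusionMatrix, report: AgreementReport) -> str:
    """Human-readable row-percent confusion table with summary lines."""
    names = cm.state_names
    width = max(len(s) for s in names) + 2
    lines = ["Manual scoring rows vs predicted columns (row %)"]
    lines.append(" " * width + "".join(f"{s:>8}" for s in names))
    rp = cm.row_percent()
    for i, s in enumerate(names):
        cells = "".join("     -  " if np.isnan(v) else f"{v:8.2f}" for v in rp[i])
        lines.append(f"{s:<{width}}" + cells)
    sens = ", ".join(
        f"{s}: {'-' if np.isnan(v) else format(v, '.2f') + '%'}"
        for s, v in zip(names, report.per_stage_sensitivity))
    lines.append(f"Sensitivity  {sens}")
    lines.append(f"Overall agreement M_SSRR = {report.m_ssrr:.2f}%  "
                 f"kappa = {report.kappa:.3f} ({report.kappa_band})")
    return "\n".join(lines)


def write_report_json(cm: ConfusionMatrix, report: AgreementReport,
                      path: str | Path) -> None:
    payload = report.to_dict()
    payload["confusion_counts"] = cm.counts.tolist()
    payload["state_names"] = list(cm.state_names)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def cross_validate(subjects: Sequence[tuple[np.ndarray, Hypnogram]],
                   mask: TransitionMask, m: int = 50, n_repeats: int = 5,
                   seed: int = 0, smoothing: float = 1.0) -> list[AgreementReport]:
    """Repeated 2-fold cross-validation over per-subject feature data.

    Each subject is an (epoch x 13 feature matrix, reference hypnogram)
    pair. Per repeat the subject list is shuffled and split in half;
    each half in turn trains the codebook and the supervised DHMM and
    the other half is decoded. Returns one fold-level report per
    (repeat, fold) — 2 x n_repeats reports.
    """
    from .pipeline import train_fold, score_fold  # local import: avoid cycle

    if len(subjects) < 2:
        raise ValueError("cross-validation needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    reports: list[AgreementReport] = []
    for rep in range(n_repeats):
        order = rng.permutation(len(subjects))
        half = len(subjects) // 2
        folds = (order[:half], order[half:])
        for test_ids, train_ids in ((folds[0], folds[1]), (folds[1], folds[0])):
            train_set = [subjects[i] for i in train_ids]
            test_set = [subjects[i] for i in test_ids]
            model, cb = train_fold(train_set, mask, m=m,
                                   seed=int(rng.integers(2 ** 31)),
                                   smoothing=smoothing)
            cm = score_fold(model, cb, test_set)
            reports.append(agreement_report(cm))
    return reports
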