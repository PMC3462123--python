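"""End-to-end orchestration: featurize recordings, train the codebook
and the constrained DHMM, decode, and report agreement.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .codebook import Codebook, encode, train_codebook
from .config import PipelineConfig
from .dhmm import DHMMModel, decode, train
from .evaluate import (AgreementReport, ConfusionMatrix, agreement_report,
                       confusion, format_report)
from .features import feature_matrix, write_features_tsv
from .preprocess import detect_movement, preprocess_recording, segment_epochs
from .stages import Hypnogram, TransitionMask
from .synth import PSGRecording

logger = logging.getLogger("sleepdhmm")


def featurize_recording(recording: PSGRecording,
                        zero_phase: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess + segment + extract features.

    Returns the (n_epochs, 13) feature matrix and a boolean movement
    flag per epoch (EEG amplitude over 200 μV).
    """
    conditioned = preprocess_recording(recording, zero_phase=zero_phase)
    epochs = segment_epochs(conditioned)
    movement = np.array([detect_movement(e) for e in epochs], dtype=bool)
    return feature_matrix(epochs), movement


def train_fold(train_set: Sequence[tuple[np.ndarray, Hypnogram]],
               mask: TransitionMask, m: int, seed: int,
               smoothing: float = 1.0) -> tuple[DHMMModel, Codebook]:
    """Codebook + supervised DHMM from feature/label pairs."""
    all_features = np.vstack([f for f, _ in train_set])
    cb, _ = train_codebook(all_features, m=m, seed=seed)
    obs = [encode(f, cb) for f, _ in train_set]
    labels = [h.indices(mask.state_names) for _, h in train_set]
    model = train(obs, labels, mask, m=m, smoothing=smoothing)
    return model, cb


def score_fold(model: DHMMModel, cb: Codebook,
               test_set: Sequence[tuple[np.ndarray, Hypnogram]]) -> ConfusionMatrix:
    """Decode every test subject and pool the confusion counts."""
    total = np.zeros((model.n_states, model.n_states), dtype=np.int64)
    for features, reference in test_set:
        predicted = decode(model, encode(features, cb))
        total += confusion(reference, predicted, model.mask.state_names).counts
    return ConfusionMatrix(counts=total, state_names=model.mask.state_names)


def run_pipeline(config: PipelineConfig,
                 recordings: Sequence[PSGRecording],
                 hypnograms: Sequence[Hypnogram],
                 out_dir: str | Path | None = None,
                 ) -> tuple[DHMMModel, Codebook, list[Hypnogram], AgreementReport]:
    """Train on labeled recordings and score the training fit.

    Runs the five staging steps in order (codebook, DHMM training,
    quantization, forward scoring, Viterbi backtracking), optionally
    writing every artifact plus a checksum manifest under ``out_dir``.
    """
    if len(recordings) != len(hypnograms):
        raise ValueError("recordings and hypnograms count mismatch")
    if not recordings:
        raise ValueError("no recordings")
    mask = config.mask()

    subjects: list[tuple[np.ndarray, Hypnogram]] = []
    for rec, hyp in zip(recordings, hypnograms):
        try:
            feats, movement = featurize_recording(rec, zero_phase=config.zero_phase)
        except Exception as exc:
            raise RuntimeError(f"featurize failed for subject {rec.subject_id}: {exc}") from exc
        if len(feats) != len(hyp):
            raise ValueError(
                f"subject {rec.subject_id}: {len(feats)} epochs vs "
                f"{len(hyp)} hypnogram labels")
        if config.exclude_movement and movement.any():
            keep = ~movement
            feats = feats[keep]
            hyp = Hypnogram(stages=tuple(s for s, k in zip(hyp, keep) if k))
        subjects.append((feats, hyp))

    model, cb = train_fold(subjects, mask, m=config.m, seed=config.seed,
                           smoothing=config.smoothing)
    decoded = [decode(model, encode(f, cb)) for f, _ in subjects]
    total = np.zeros((mask.n_states, mask.n_states), dtype=np.int64)
    for (f, ref), pred in zip(subjects, decoded):
        total += confusion(ref, pred, mask.state_names).counts
    cm = ConfusionMatrix(counts=total, state_names=mask.state_names)
    report = agreement_report(cm)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        cb.to_json(out_dir / "codebook.json"); written.append(out_dir / "codebook.json")
        model.to_json(out_dir / "model.json"); written.append(out_dir / "model.json")
        mask.to_json(out_dir / "mask.json"); written.append(out_dir / "mask.json")
        config.to_json(out_dir / "config.json"); written.append(out_dir / "config.json")
        for rec, pred in zip(recordings, decoded):
            p = out_dir / f"{rec.subject_id}.decoded.tsv"
            pred.to_tsv(p)
            written.append(p)
        from .evaluate import write_report_json
        write_report_json(cm, report, out_dir / "report.json")
        written.append(out_dir / "report.json")
        from .io import sha256_of
        manifest = {p.name: sha256_of(p) for p in written}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        logger.info("pipeline artifacts written to %s", out_dir)

    logger.info("pipeline done:\n%s", format_report(cm, report))
    return model, cb, decoded, report
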