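"""Vector quantization of 13-dim feature vectors.

Initialization follows the subinterval scheme: each feature dimension's
training range is split into m equal subintervals and center k draws
each coordinate uniformly inside its k-th subinterval. Training is the
plain two-step k-means alternation with Euclidean distance; empty
groups keep their stale center so the codebook stays size m. Codes are
1-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 300


@dataclass(frozen=True)
class Codebook:
    """m centroid vectors plus the per-dimension training ranges."""

    centers: np.ndarray            # (m, d)
    feature_ranges: np.ndarray     # (d, 2) lower/upper bounds

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        ranges = np.asarray(self.feature_ranges, dtype=float)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "feature_ranges", ranges)
        if centers.ndim != 2 or centers.shape[0] < 1:
            raise ValueError("centers must be a nonempty 2-D array")
        if not np.all(np.isfinite(centers)):
            raise ValueError("non-finite centers")
        if ranges.shape != (centers.shape[1], 2):
            raise ValueError("feature_ranges must be (d, 2)")

    @property
    def m(self) -> int:
        return self.centers.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "m": self.m,
            "feature_ranges": self.feature_ranges.tolist(),
            "centers": self.centers.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        payload = json.loads(Path(path).read_text())
        cb = cls(centers=np.array(payload["centers"], dtype=float),
                 feature_ranges=np.array(payload["feature_ranges"], dtype=float))
        if cb.m != payload["m"]:
            raise ValueError(f"{path}: m={payload['m']} does not match centers")
        return cb


def init_codebook(feature_vectors: np.ndarray, m: int, seed: int) -> Codebook:
    """Subinterval-random initial codebook from training feature ranges."""
    X = np.asarray(feature_vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature_vectors must be 2-D")
    if m < 1:
        raise ValueError("m must be >= 1")
    if X.shape[0] < m:
        raise ValueError(f"need at least m={m} training vectors, got {X.shape[0]}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    width = (hi - lo) / m
    rng = np.random.default_rng(seed)
    k = np.arange(m)[:, None]
    low_edges = lo[None, :] + k * width[None, :]
    centers = low_edges + rng.uniform(size=(m, X.shape[1])) * width[None, :]
    return Codebook(centers=centers, feature_ranges=np.column_stack([lo, hi]))


def assign(v_f: np.ndarray, codebook: Codebook) -> int:
    """1-based code of the nearest center; ties go to the lowest code."""
    d = np.sum((codebook.centers - np.asarray(v_f, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d)) + 1


def quantization_error(X: np.ndarray, codebook: Codebook) -> float:
    """Mean squared distance of each vector to its assigned center."""
    d2 = cdist(np.asarray(X, dtype=float), codebook.centers, "sqeuclidean")
    return float(d2.min(axis=1).mean())


def train_codebook(feature_vectors: np.ndarray, m: int, seed: int,
                   max_iter: int = DEFAULT_MAX_ITER,
                   tol: float = DEFAULT_TOL) -> tuple[Codebook, list[float]]:
    """k-means alternation from the subinterval init.

    Returns the trained codebook and the per-iteration quantization
    error history (non-increasing).
    """
    X = np.asarray(feature_vectors, dtype=float)
    if X.size == 0:
        raise ValueError("empty training data")
    cb = init_codebook(X, m, seed)
    centers = cb.centers.copy()
    history: list[float] = []
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(len(X)), labels].mean()))
        new_centers = centers.copy()
        for k in range(m):
            members = X[labels == k]
            if len(members):
                new_centers[k] = members.mean(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    trained = Codebook(centers=centers, feature_ranges=cb.feature_ranges)
    history.append(quantization_error(X, trained))
    return trained, history


def encode(feature_matrix: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Order-preserving 1-based codes, one per epoch row."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.size == 0:
        return np.empty(0, dtype=np.int64)
    d2 = cdist(X, codebook.centers, "sqeuclidean")
    return d2.argmin(axis=1).astype(np.int64) + 1


def write_codes_tsv(codes: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index\tcode\n")
        for i, c in enumerate(codes):
            fh.write(f"{i}\t{int(c)}\n")


def read_codes_tsv(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["epoch_index", "code"]:
            raise ValueError(f"{path}: unexpected columns")
        data = np.loadtxt(fh, delimiter="\t", dtype=np.int64, ndmin=2)
    if data.size == 0:
        return np.empty(0, dtype=np.int64)
    return data[:, 1]
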