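"""Transition-constrained discrete HMM.

Model representation, brute-force likelihood (small-instance oracle),
scaled Forward recursion, log-space Viterbi decoding, and count-based
training in which transitions disallowed by the mask are pinned to
exactly zero.

Observation codes are 1-based integers in [1, M], matching the codebook.
State indices follow the fixed stage order of the mask.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .stages import Hypnogram, TransitionMask

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DHMMModel:
    """lambda = (A, B, pi) with an allowed-transition mask.

    ``B[j, k]`` is the probability that state j emits code k+1.
    """

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray
    mask: TransitionMask

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "pi", pi)
        n = self.mask.n_states
        if A.shape != (n, n):
            raise ValueError(f"A shape {A.shape} != ({n}, {n})")
        if B.ndim != 2 or B.shape[0] != n:
            raise ValueError(f"B must be ({n}, M)")
        if pi.shape != (n,):
            raise ValueError(f"pi shape {pi.shape} != ({n},)")
        if np.abs(A.sum(axis=1) - 1.0).max() > _SUM_TOL:
            raise ValueError("rows of A must sum to 1")
        if np.abs(B.sum(axis=1) - 1.0).max() > _SUM_TOL:
            raise ValueError("per-state emission probabilities must sum to 1")
        if abs(pi.sum() - 1.0) > _SUM_TOL:
            raise ValueError("pi must sum to 1")
        if np.any(A[~self.mask.allowed] != 0.0):
            raise ValueError("A has nonzero probability on a masked transition")

    @property
    def n_states(self) -> int:
        return self.mask.n_states

    @property
    def M(self) -> int:
        return self.B.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "state_names": list(self.mask.state_names),
            "M": self.M,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "pi": self.pi.tolist(),
            "mask": self.mask.allowed.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DHMMModel":
        payload = json.loads(Path(path).read_text())
        mask = TransitionMask(allowed=np.array(payload["mask"], dtype=bool),
                              state_names=tuple(payload["state_names"]))
        return cls(A=np.array(payload["A"]), B=np.array(payload["B"]),
                   pi=np.array(payload["pi"]), mask=mask)


@dataclass(frozen=True)
class TransitionCounts:
    """Raw event counts from paired state/observation sequences."""

    n_ij: np.ndarray   # (N, N) state-to-state transitions
    n_jk: np.ndarray   # (N, M) state j emitting code k+1
    n_h: np.ndarray    # (N,) initial-state occurrences
    n_TD: int          # number of training sequences


@dataclass(frozen=True)
class Trellis:
    """Dynamic-programming lattice: scaled alphas or log-deltas."""

    values: np.ndarray                 # (T, N)
    scaling: np.ndarray | None = None  # (T,) forward scaling factors
    psi: np.ndarray | None = None      # (T, N) Viterbi backpointers


def _codes(obs: Sequence[int], M: int) -> np.ndarray:
    o = np.asarray(obs, dtype=np.int64)
    if o.ndim != 1 or len(o) < 1:
        raise ValueError("observation sequence must be a nonempty 1-D sequence")
    if o.min() < 1 or o.max() > M:
        bad = o[(o < 1) | (o > M)][0]
        raise ValueError(f"observation code {bad} outside [1, {M}]")
    return o - 1


def likelihood_bruteforce(model: DHMMModel, obs: Sequence[int]) -> float:
    """P(O | lambda) by explicit summation over all state sequences.

    Exponential in T; guarded to tiny instances. This is the oracle the
    Forward recursion is checked against, not a production path.
    """
    o = _codes(obs, model.M)
    T, N = len(o), model.n_states
    if T > 8 or N > 5:
        raise ValueError(f"brute force restricted to T <= 8, N <= 5 (got T={T}, N={N})")
    total = 0.0
    for q in itertools.product(range(N), repeat=T):
        p = model.pi[q[0]] * model.B[q[0], o[0]]
        for t in range(1, T):
            p *= model.A[q[t - 1], q[t]] * model.B[q[t], o[t]]
        total += p
    return total


def forward(model: DHMMModel, obs: Sequence[int]) -> tuple[float, Trellis]:
    """Scaled Forward recursion; returns log P(O | lambda) and the lattice.

    Each step's alpha column is normalized to sum 1 and the scale factor
    retained, so the log-likelihood is the sum of log scales and stays
    finite for arbitrarily long sequences.
    """
    o = _codes(obs, model.M)
    T, N = len(o), model.n_states
    alpha = np.empty((T, N))
    scales = np.empty(T)
    a = model.pi * model.B[:, o[0]]
    c = a.sum()
    if c == 0.0:
        return -np.inf, Trellis(values=np.zeros((T, N)), scaling=np.zeros(T))
    alpha[0] = a / c
    scales[0] = c
    AT = model.A
    for t in range(1, T):
        a = (alpha[t - 1] @ AT) * model.B[:, o[t]]
        c = a.sum()
        if c == 0.0:
            return -np.inf, Trellis(values=alpha, scaling=scales)
        alpha[t] = a / c
        scales[t] = c
    return float(np.log(scales).sum()), Trellis(values=alpha, scaling=scales)


def viterbi(model: DHMMModel, obs: Sequence[int]) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log-probability.

    Log-space recursion; masked transitions (A == 0) carry -inf weight
    and can never appear on the returned path.
    """
    o = _codes(obs, model.M)
    T, N = len(o), model.n_states
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logB = np.log(model.B)
        logpi = np.log(model.pi)
    delta = np.empty((T, N))
    psi = np.zeros((T, N), dtype=np.int64)
    delta[0] = logpi + logB[:, o[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + logA      # cand[i, j]
        psi[t] = cand.argmax(axis=0)
        delta[t] = cand[psi[t], np.arange(N)] + logB[:, o[t]]
    log_p = float(delta[T - 1].max())
    if not np.isfinite(log_p):
        raise ValueError("no positive-probability state path for this observation sequence")
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = int(delta[T - 1].argmax())
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, log_p


def decode(model: DHMMModel, obs: Sequence[int]) -> Hypnogram:
    """Viterbi path as a stage-labeled hypnogram."""
    path, _ = viterbi(model, obs)
    return Hypnogram.from_indices(path, model.mask.state_names)


def count_events(state_sequences: Sequence[Sequence[int]],
                 obs_sequences: Sequence[Sequence[int]],
                 N: int, M: int) -> TransitionCounts:
    """Exact transition/emission/initial counts over paired sequences."""
    if len(state_sequences) != len(obs_sequences):
        raise ValueError("number of state and observation sequences differ")
    n_ij = np.zeros((N, N), dtype=np.int64)
    n_jk = np.zeros((N, M), dtype=np.int64)
    n_h = np.zeros(N, dtype=np.int64)
    for states, obs in zip(state_sequences, obs_sequences):
        q = np.asarray(states, dtype=np.int64)
        o = _codes(obs, M)
        if len(q) != len(o):
            raise ValueError(
                f"state sequence length {len(q)} != observation length {len(o)}")
        n_h[q[0]] += 1
        np.add.at(n_ij, (q[:-1], q[1:]), 1)
        np.add.at(n_jk, (q, o), 1)
    return TransitionCounts(n_ij=n_ij, n_jk=n_jk, n_h=n_h,
                            n_TD=len(state_sequences))


def update_parameters(counts: TransitionCounts, mask: TransitionMask,
                      smoothing: float = 1.0) -> DHMMModel:
    """Count-ratio parameter estimates with masked cells pinned to zero.

    A rows are raw transition frequencies restricted to allowed cells
    and renormalized; emissions get ``smoothing`` Laplace pseudo-counts
    so codes unseen in training keep nonzero probability; pi is the
    initial-state frequency.
    """
    N = mask.n_states
    M = counts.n_jk.shape[1]
    if counts.n_TD < 1:
        raise ValueError("no training sequences")

    masked_counts = np.where(mask.allowed, counts.n_ij, 0).astype(float)
    row_sums = masked_counts.sum(axis=1)
    A = np.zeros((N, N))
    for i in range(N):
        if row_sums[i] > 0:
            A[i] = masked_counts[i] / row_sums[i]
        elif smoothing > 0:
            A[i, mask.allowed[i]] = 1.0 / mask.allowed[i].sum()
        else:
            raise ValueError(
                f"state {mask.state_names[i]} has no outgoing transition counts "
                "and smoothing is disabled")

    col = counts.n_jk.sum(axis=1, keepdims=True).astype(float)
    B = (counts.n_jk + smoothing) / (col + M * smoothing)
    if smoothing == 0:
        zero = (col[:, 0] == 0)
        if zero.any():
            j = int(np.flatnonzero(zero)[0])
            raise ValueError(
                f"state {mask.state_names[j]} has no emission counts "
                "and smoothing is disabled")

    pi = counts.n_h / counts.n_TD
    return DHMMModel(A=A, B=B, pi=pi, mask=mask)


def sample(model: DHMMModel, T: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (state sequence, 1-based observation codes) pair of length T."""
    rng = np.random.default_rng(seed)
    N, M = model.n_states, model.M
    states = np.empty(T, dtype=np.int64)
    obs = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(N, p=model.pi)
    obs[0] = rng.choice(M, p=model.B[states[0]]) + 1
    for t in range(1, T):
        states[t] = rng.choice(N, p=model.A[states[t - 1]])
        obs[t] = rng.choice(M, p=model.B[states[t]]) + 1
    return states, obs


def _uniform_model(mask: TransitionMask, M: int, seed: int) -> DHMMModel:
    """Near-uniform masked model with a seeded perturbation to break ties."""
    rng = np.random.default_rng(seed)
    N = mask.n_states
    A = mask.allowed * (1.0 + 0.01 * rng.uniform(size=(N, N)))
    A[~mask.allowed] = 0.0
    A /= A.sum(axis=1, keepdims=True)
    B = 1.0 + 0.01 * rng.uniform(size=(N, M))
    B /= B.sum(axis=1, keepdims=True)
    pi = np.full(N, 1.0 / N)
    return DHMMModel(A=A, B=B, pi=pi, mask=mask)


def joint_log_likelihood(model: DHMMModel, states: np.ndarray,
                         obs: Sequence[int]) -> float:
    """log P(O, Q | lambda) for one fully observed path."""
    o = _codes(obs, model.M)
    q = np.asarray(states, dtype=np.int64)
    with np.errstate(divide="ignore"):
        ll = np.log(model.pi[q[0]]) + np.log(model.B[q[0], o[0]])
        if len(q) > 1:
            ll += np.log(model.A[q[:-1], q[1:]]).sum()
            ll += np.log(model.B[q[1:], o[1:]]).sum()
    return float(ll)


def train(obs_sequences: Sequence[Sequence[int]],
          labels: Sequence[Sequence[int]] | None,
          mask: TransitionMask, m: int,
          seed: int = 0, max_iter: int = 50, tol: float = 1e-6,
          smoothing: float = 1.0,
          initial_model: DHMMModel | None = None) -> DHMMModel:
    """Train the constrained DHMM.

    Supervised mode (``labels`` given): a single counting pass over the
    expert-scored sequences. Unsupervised refinement (``labels`` None):
    hard re-estimation — decode with the current model, recount, update
    — iterated until the largest parameter change drops below ``tol``.
    The decoded-path joint log-likelihood history is checked to be
    non-decreasing (small slack for emission smoothing).
    """
    if len(obs_sequences) == 0:
        raise ValueError("no training sequences")
    if labels is not None:
        if len(labels) != len(obs_sequences):
            raise ValueError("labels and observations count mismatch")
        counts = count_events(labels, obs_sequences, mask.n_states, m)
        return update_parameters(counts, mask, smoothing=smoothing)

    model = initial_model or _uniform_model(mask, m, seed)
    prev_ll = -np.inf
    for _ in range(max_iter):
        paths = [viterbi(model, o)[0] for o in obs_sequences]
        counts = count_events(paths, obs_sequences, mask.n_states, m)
        new_model = update_parameters(counts, mask, smoothing=smoothing)
        ll = sum(joint_log_likelihood(new_model, q, o)
                 for q, o in zip(paths, obs_sequences))
        if ll < prev_ll - 1e-6 * (1.0 + abs(prev_ll)):
            raise AssertionError(
                f"joint log-likelihood decreased during refinement: {prev_ll} -> {ll}")
        prev_ll = ll
        delta = max(np.abs(new_model.A - model.A).max(),
                    np.abs(new_model.B - model.B).max(),
                    np.abs(new_model.pi - model.pi).max())
        model = new_model
        if delta < tol:
            break
    return model
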