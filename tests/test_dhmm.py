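import itertools

import numpy as np
import pytest

from sleepdhmm.dhmm import (DHMMModel, TransitionCounts, count_events, decode,
                            forward, joint_log_likelihood,
                            likelihood_bruteforce, sample, train,
                            update_parameters, viterbi)
from sleepdhmm.stages import STAGES_5, TransitionMask, default_mask
from sleepdhmm.synth import balanced_transition_matrix


def full_mask(n):
    names = tuple(f"q{i}" for i in range(n)) if n != 5 else STAGES_5
    return TransitionMask(allowed=np.ones((n, n), dtype=bool), state_names=names)


def random_model(seed, n=3, m=4, mask=None):
    rng = np.random.default_rng(seed)
    mask = mask or full_mask(n)
    n = mask.n_states
    A = rng.uniform(0.1, 1.0, size=(n, n)) * mask.allowed
    A /= A.sum(axis=1, keepdims=True)
    B = rng.uniform(0.1, 1.0, size=(n, m))
    B /= B.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.1, 1.0, size=n)
    pi /= pi.sum()
    return DHMMModel(A=A, B=B, pi=pi, mask=mask)


def enumerate_best_path(model, obs):
    """Independent exhaustive Viterbi oracle."""
    o = np.asarray(obs) - 1
    best, best_p = None, -np.inf
    for q in itertools.product(range(model.n_states), repeat=len(o)):
        p = model.pi[q[0]] * model.B[q[0], o[0]]
        for t in range(1, len(o)):
            p *= model.A[q[t - 1], q[t]] * model.B[q[t], o[t]]
        if p > best_p:
            best, best_p = q, p
    return np.array(best), np.log(best_p) if best_p > 0 else -np.inf


def recursive_likelihood(model, obs):
    """Second independent oracle: recursion over the sequence tail."""
    o = np.asarray(obs) - 1

    def rec(t, i):
        emit = model.B[i, o[t]]
        if t == len(o) - 1:
            return emit
        return emit * sum(model.A[i, j] * rec(t + 1, j)
                          for j in range(model.n_states))

    return sum(model.pi[i] * rec(0, i) for i in range(model.n_states))


class TestBruteForce:
    def test_t1_closed_form(self):
        model = random_model(0)
        for o in range(1, model.M + 1):
            expected = float((model.pi * model.B[:, o - 1]).sum())
            assert likelihood_bruteforce(model, [o]) == pytest.approx(expected)

    def test_deterministic_chain(self):
        mask = full_mask(2)
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        B = np.eye(2)
        pi = np.array([1.0, 0.0])
        model = DHMMModel(A=A, B=B, pi=pi, mask=mask)
        assert likelihood_bruteforce(model, [1, 2, 1]) == pytest.approx(1.0)
        assert likelihood_bruteforce(model, [1, 1, 1]) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_recursion(self, seed):
        model = random_model(seed, n=3, m=4)
        obs = np.random.default_rng(seed).integers(1, 5, size=5)
        assert likelihood_bruteforce(model, obs) == pytest.approx(
            recursive_likelihood(model, obs), rel=1e-12)

    def test_size_guard(self):
        model = random_model(1)
        with pytest.raises(ValueError, match="T <= 8"):
            likelihood_bruteforce(model, [1] * 9)


class TestForward:
    def test_t1_single_state(self):
        mask = full_mask(2)
        B = np.array([[0.5, 0.5], [0.9, 0.1]])
        model = DHMMModel(A=np.full((2, 2), 0.5), B=B,
                          pi=np.array([1.0, 0.0]), mask=mask)
        logp, _ = forward(model, [1])
        assert logp == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(seed, n=int(rng.integers(2, 6)),
                             m=int(rng.integers(2, 7)))
        T = int(rng.integers(1, 9))
        obs = rng.integers(1, model.M + 1, size=T)
        logp, _ = forward(model, obs)
        assert np.exp(logp) == pytest.approx(
            likelihood_bruteforce(model, obs), rel=1e-10)

    def test_masked_equals_explicit_zero(self):
        mask = default_mask()
        model = random_model(3, m=5, mask=mask)
        unmasked = DHMMModel(A=model.A, B=model.B, pi=model.pi,
                             mask=full_mask(5))
        obs = np.random.default_rng(3).integers(1, 6, size=50)
        assert forward(model, obs)[0] == pytest.approx(
            forward(unmasked, obs)[0], rel=1e-12)

    def test_out_of_range_code(self):
        model = random_model(4)
        with pytest.raises(ValueError, match="outside"):
            forward(model, [1, 99])

    def test_scaling_long_sequence_finite(self):
        model = random_model(5, n=5, m=6)
        obs = np.random.default_rng(5).integers(1, 7, size=5000)
        logp, trellis = forward(model, obs)
        assert np.isfinite(logp)
        assert logp == pytest.approx(np.log(trellis.scaling).sum())
        assert logp < 0


class TestViterbi:
    def test_deterministic_model(self):
        mask = full_mask(2)
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        model = DHMMModel(A=A, B=np.eye(2), pi=np.array([1.0, 0.0]), mask=mask)
        path, logp = viterbi(model, [1, 2, 1, 2])
        np.testing.assert_array_equal(path, [0, 1, 0, 1])
        assert logp == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(1000 + seed)
        model = random_model(seed, n=int(rng.integers(2, 6)),
                             m=int(rng.integers(2, 7)))
        T = int(rng.integers(1, 9))
        obs = rng.integers(1, model.M + 1, size=T)
        path, logp = viterbi(model, obs)
        best, best_logp = enumerate_best_path(model, obs)
        assert logp == pytest.approx(best_logp, rel=1e-10)
        np.testing.assert_array_equal(path, best)

    def test_no_wake_to_sws_step(self):
        mask = default_mask()
        model = random_model(6, m=8, mask=mask)
        rng = np.random.default_rng(6)
        obs = rng.integers(1, 9, size=2000)
        path, _ = viterbi(model, obs)
        for t in range(len(path) - 1):
            assert mask.allowed[path[t], path[t + 1]]

    def test_impossible_observation_rejected(self):
        mask = full_mask(2)
        B = np.array([[1.0, 0.0], [1.0, 0.0]])  # code 2 never emitted
        model = DHMMModel(A=np.full((2, 2), 0.5), B=B,
                          pi=np.array([0.5, 0.5]), mask=mask)
        with pytest.raises(ValueError, match="no positive-probability"):
            viterbi(model, [1, 2])


class TestCountEvents:
    def test_hand_count(self):
        counts = count_events([[0, 0, 1]], [[1, 2, 1]], N=2, M=2)
        assert counts.n_ij[0, 0] == 1 and counts.n_ij[0, 1] == 1
        assert counts.n_h[0] == 1 and counts.n_h[1] == 0
        assert counts.n_TD == 1
        assert counts.n_jk[0, 0] == 1 and counts.n_jk[0, 1] == 1
        assert counts.n_jk[1, 0] == 1

    def test_empty(self):
        counts = count_events([], [], N=3, M=4)
        assert counts.n_TD == 0
        assert not counts.n_ij.any() and not counts.n_jk.any() and not counts.n_h.any()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            count_events([[0, 1]], [[1]], N=2, M=2)

    def test_frequencies_within_3se(self, mask):
        A = balanced_transition_matrix(mask)
        pi = np.full(5, 0.2)
        model = DHMMModel(A=A, B=np.full((5, 4), 0.25), pi=pi, mask=mask)
        seqs, obs = zip(*(sample(model, 900, seed=s) for s in range(10)))
        counts = count_events(seqs, obs, N=5, M=4)
        ahat = counts.n_ij / counts.n_ij.sum(axis=1, keepdims=True)
        row = counts.n_ij.sum(axis=1)
        for i in range(5):
            for j in range(5):
                se = np.sqrt(A[i, j] * (1 - A[i, j]) / row[i])
                assert abs(ahat[i, j] - A[i, j]) <= max(3 * se, 1e-12)


class TestUpdateParameters:
    def test_direct_division(self):
        # A and pi are raw count ratios (smoothing touches B only)
        counts = count_events([[0, 0, 1]], [[1, 2, 1]], N=2, M=2)
        model = update_parameters(counts, full_mask(2), smoothing=1.0)
        assert model.A[0, 0] == pytest.approx(0.5)
        assert model.A[0, 1] == pytest.approx(0.5)
        assert model.pi[0] == 1.0

    def test_masked_cell_zeroed_and_renormalized(self):
        mask = default_mask()
        n_ij = np.zeros((5, 5), dtype=np.int64)
        n_ij[0, 0] = 6
        n_ij[0, 3] = 2  # Wake -> SWS, disallowed
        n_ij[0, 1] = 2
        for i in range(1, 5):
            n_ij[i, i] = 1
        counts = TransitionCounts(n_ij=n_ij, n_jk=np.ones((5, 3), dtype=np.int64),
                                  n_h=np.array([1, 0, 0, 0, 0]), n_TD=1)
        model = update_parameters(counts, mask)
        assert model.A[0, 3] == 0.0
        assert model.A[0].sum() == pytest.approx(1.0)
        assert model.A[0, 0] == pytest.approx(6 / 8)

    def test_laplace_uniform_limit(self):
        counts = TransitionCounts(
            n_ij=np.eye(2, dtype=np.int64), n_jk=np.zeros((2, 4), dtype=np.int64),
            n_h=np.array([1, 0]), n_TD=1)
        model = update_parameters(counts, full_mask(2), smoothing=1.0)
        np.testing.assert_allclose(model.B, 0.25)

    def test_zero_row_without_smoothing_named(self):
        n_ij = np.zeros((5, 5), dtype=np.int64)
        n_ij[0, 0] = 1
        n_ij[1, 1] = n_ij[2, 2] = n_ij[4, 4] = 1
        counts = TransitionCounts(n_ij=n_ij, n_jk=np.ones((5, 2), dtype=np.int64),
                                  n_h=np.array([1, 0, 0, 0, 0]), n_TD=1)
        with pytest.raises(ValueError, match="SWS"):
            update_parameters(counts, default_mask(), smoothing=0.0)

    def test_conservation_fuzz(self):
        # normalization invariants hold across random count tables
        rng = np.random.default_rng(8)
        mask = default_mask()
        for _ in range(100):
            counts = TransitionCounts(
                n_ij=rng.integers(0, 50, size=(5, 5)),
                n_jk=rng.integers(0, 50, size=(5, 7)),
                n_h=rng.multinomial(10, np.full(5, 0.2)), n_TD=10)
            model = update_parameters(counts, mask, smoothing=1.0)
            np.testing.assert_allclose(model.A.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(model.B.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(model.A[~mask.allowed] == 0.0)


class TestTrain:
    def make_truth(self, mask, m=6, seed=0):
        rng = np.random.default_rng(seed)
        A = balanced_transition_matrix(mask)
        B = rng.uniform(0.05, 1.0, size=(5, m))
        B /= B.sum(axis=1, keepdims=True)
        pi = np.full(5, 0.2)
        return DHMMModel(A=A, B=B, pi=pi, mask=mask)

    def test_supervised_recovery(self, mask):
        truth = self.make_truth(mask)
        seqs, obs = zip(*(sample(truth, 900, seed=s) for s in range(10)))
        model = train(list(obs), list(seqs), mask, m=truth.M)
        err = np.abs((model.A - truth.A)[mask.allowed]).max()
        assert err <= 0.03

    def separable_truth(self, mask):
        # each state has its own dominant emission code
        B = np.full((5, 5), 0.02)
        np.fill_diagonal(B, 0.92)
        return DHMMModel(A=balanced_transition_matrix(mask), B=B,
                         pi=np.full(5, 0.2), mask=mask)

    def test_refinement_fixed_point(self, mask):
        truth = self.separable_truth(mask)
        seqs, obs = zip(*(sample(truth, 500, seed=200 + s) for s in range(4)))
        converged = train(list(obs), None, mask, m=5, max_iter=50,
                          initial_model=truth)
        again = train(list(obs), None, mask, m=5, max_iter=5,
                      initial_model=converged)
        # a converged refinement is an exact fixed point of hard EM
        assert np.abs(again.A - converged.A).max() == 0.0
        assert np.abs(again.B - converged.B).max() == 0.0

    def test_refinement_close_to_supervised(self, mask):
        truth = self.separable_truth(mask)
        seqs, obs = zip(*(sample(truth, 500, seed=200 + s) for s in range(4)))
        supervised = train(list(obs), list(seqs), mask, m=5)
        # refine from a model supervised on only the first sequence
        partial = train([obs[0]], [seqs[0]], mask, m=5)
        refined = train(list(obs), None, mask, m=5, max_iter=30,
                        initial_model=partial)
        sup_acc = np.mean([np.mean(viterbi(supervised, o)[0] == q)
                           for q, o in zip(seqs, obs)])
        ref_acc = np.mean([np.mean(viterbi(refined, o)[0] == q)
                           for q, o in zip(seqs, obs)])
        assert ref_acc >= sup_acc - 0.05

    def test_consistency_error_halves(self, mask):
        truth = self.make_truth(mask, seed=2)

        def mean_err(T, base_seed):
            errs = []
            for s in range(6):
                seqs, obs = zip(*(sample(truth, T, seed=base_seed + 37 * s + k)
                                  for k in range(4)))
                model = train(list(obs), list(seqs), mask, m=truth.M)
                errs.append(np.abs((model.A - truth.A)[mask.allowed]).max())
            return np.mean(errs)

        e1 = mean_err(500, 1000)
        e2 = mean_err(2000, 5000)
        assert 0.35 <= e2 / e1 <= 0.65

    def test_no_sequences_rejected(self, mask):
        with pytest.raises(ValueError, match="no training"):
            train([], [], mask, m=3)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, tmp_path, mask):
        model = random_model(9, m=11, mask=mask)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = DHMMModel.from_json(p)
        assert np.array_equal(back.A, model.A)
        assert np.array_equal(back.B, model.B)
        assert np.array_equal(back.pi, model.pi)
        assert np.array_equal(back.mask.allowed, model.mask.allowed)
        assert back.mask.state_names == model.mask.state_names

    def test_invariant_validation(self, mask):
        A = np.full((5, 5), 0.2)
        with pytest.raises(ValueError, match="masked"):
            DHMMModel(A=A, B=np.full((5, 2), 0.5), pi=np.full(5, 0.2), mask=mask)


class TestJointLogLikelihood:
    def test_matches_manual_product(self):
        model = random_model(10, n=3, m=3)
        q = np.array([0, 2, 1])
        o = [1, 3, 2]
        manual = (np.log(model.pi[0]) + np.log(model.B[0, 0])
                  + np.log(model.A[0, 2]) + np.log(model.B[2, 2])
                  + np.log(model.A[2, 1]) + np.log(model.B[1, 1]))
        assert joint_log_likelihood(model, q, o) == pytest.approx(manual)
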