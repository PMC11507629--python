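"""Linear-chain CRF: scoring, partition, gradients, Viterbi vs enumeration."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from sslabel.crf import (
    CrfParameters, brute_force_oracle, crf_nll_batch, forward_backward,
    log_partition, nll_gradients, nll_loss, score_path, viterbi_decode,
)
from sslabel.autodiff import Tensor

from conftest import random_crf_instance


# the K=2, L=3 instance whose path scores are small enough to sum by hand
HAND_EMISSIONS = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
HAND_PARAMS = CrfParameters(
    transitions=np.array([[2.0, 0.0], [0.0, 2.0]]),
    start=np.zeros(2),
    stop=np.zeros(2),
)


def hand_enumeration_scores():
    """Independent in-test enumeration: plain Python loop over 2^3 paths."""
    scores = {}
    for path in itertools.product(range(2), repeat=3):
        s = sum(HAND_EMISSIONS[t, y] for t, y in enumerate(path))
        s += sum(HAND_PARAMS.transitions[a, b] for a, b in zip(path, path[1:]))
        scores[path] = s
    return scores


class TestScorePath:
    def test_hand_sum(self):
        # 1 + 0 + 1 (emissions) + 2 + 2 (transitions) = 6
        assert score_path(HAND_EMISSIONS, [0, 0, 0], HAND_PARAMS) == pytest.approx(6.0)

    def test_single_position_is_emission(self):
        p = CrfParameters.zeros(3)
        em = np.array([[0.3, -1.2, 0.9]])
        for k in range(3):
            assert score_path(em, [k], p) == pytest.approx(em[0, k])

    def test_zero_everything_scores_zero(self):
        p = CrfParameters.zeros(4)
        em = np.zeros((5, 4))
        for path in [[0] * 5, [3, 2, 1, 0, 3]]:
            assert score_path(em, path, p) == 0.0

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            score_path(np.zeros((0, 2)), [], CrfParameters.zeros(2))

    def test_label_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            score_path(np.zeros((2, 2)), [0, 2], CrfParameters.zeros(2))


class TestLogPartition:
    def test_uniform_single_position(self):
        assert log_partition(np.zeros((1, 3)), CrfParameters.zeros(3)) == pytest.approx(
            np.log(3.0), abs=1e-12
        )

    def test_hand_instance_matches_in_test_enumeration(self):
        expected = logsumexp(list(hand_enumeration_scores().values()))
        assert log_partition(HAND_EMISSIONS, HAND_PARAMS) == pytest.approx(
            expected, abs=1e-12
        )

    def test_emission_shift_identity(self, rng):
        em, p = random_crf_instance(rng, L=7, K=3)
        c = 0.731
        shifted = log_partition(em + c, p)
        assert shifted == pytest.approx(log_partition(em, p) + 7 * c, abs=1e-9)

    @pytest.mark.parametrize("L,K", [(1, 2), (3, 3), (5, 2), (6, 3), (4, 8)])
    def test_matches_enumeration(self, rng, L, K):
        for _ in range(8):
            em, p = random_crf_instance(rng, L=L, K=K)
            _, _, oracle_log_z = brute_force_oracle(em, p)
            assert log_partition(em, p) == pytest.approx(oracle_log_z, abs=1e-8)

    def test_path_probabilities_normalize(self, rng):
        for _ in range(10):
            em, p = random_crf_instance(rng, L=5, K=3)
            scores, _, _ = brute_force_oracle(em, p)
            log_z = log_partition(em, p)
            assert np.exp(scores - log_z).sum() == pytest.approx(1.0, abs=1e-8)


class TestViterbi:
    def test_hand_instance(self):
        path, score = viterbi_decode(HAND_EMISSIONS, HAND_PARAMS)
        assert path == [0, 0, 0]
        assert score == pytest.approx(6.0)

    def test_zero_transitions_reduce_to_argmax(self, rng):
        em = rng.standard_normal((9, 4))
        path, _ = viterbi_decode(em, CrfParameters.zeros(4))
        assert path == list(np.argmax(em, axis=1))

    def test_single_position(self):
        p = CrfParameters(np.zeros((3, 3)), np.array([0.0, 5.0, 0.0]),
                          np.array([1.0, 0.0, 0.0]))
        em = np.array([[2.0, 0.0, 0.0]])
        path, score = viterbi_decode(em, p)
        assert path == [1] and score == pytest.approx(5.0)

    def test_tie_break_is_all_zeros(self):
        path, score = viterbi_decode(np.zeros((6, 3)), CrfParameters.zeros(3))
        assert path == [0] * 6 and score == 0.0

    def test_returned_score_is_score_of_returned_path(self, rng):
        for _ in range(15):
            em, p = random_crf_instance(rng, L=10, K=4)
            path, score = viterbi_decode(em, p)
            assert score == pytest.approx(score_path(em, path, p), abs=1e-10)

    @pytest.mark.parametrize("L,K", [(6, 2), (5, 3), (4, 8)])
    def test_matches_enumeration(self, rng, L, K):
        for _ in range(8):
            em, p = random_crf_instance(rng, L=L, K=K)
            scores, best_path, _ = brute_force_oracle(em, p)
            path, score = viterbi_decode(em, p)
            assert score == pytest.approx(scores.max(), abs=1e-8)
            assert path == best_path


class TestOracle:
    def test_single_state_chain(self, rng):
        em, p = random_crf_instance(rng, L=4, K=1)
        scores, path, log_z = brute_force_oracle(em, p)
        assert len(scores) == 1 and path == [0, 0, 0, 0]
        assert log_z == pytest.approx(score_path(em, path, p))

    def test_scores_match_score_path_in_lex_order(self, rng):
        em, p = random_crf_instance(rng, L=3, K=2)
        scores, _, _ = brute_force_oracle(em, p)
        for i, path in enumerate(itertools.product(range(2), repeat=3)):
            assert scores[i] == pytest.approx(score_path(em, path, p), abs=1e-12)

    def test_too_large_rejected(self):
        with pytest.raises(ValueError):
            brute_force_oracle(np.zeros((30, 8)), CrfParameters.zeros(8))


class TestNll:
    def test_uniform_model(self):
        assert nll_loss(np.zeros((5, 3)), [0, 1, 2, 1, 0], CrfParameters.zeros(3)) == (
            pytest.approx(5 * np.log(3.0), abs=1e-10)
        )

    def test_hand_instance(self):
        expected = logsumexp(list(hand_enumeration_scores().values())) - 6.0
        assert nll_loss(HAND_EMISSIONS, [0, 0, 0], HAND_PARAMS) == pytest.approx(
            expected, abs=1e-10
        )

    def test_dominant_true_path_drives_loss_to_zero(self):
        y = [0, 2, 1, 1]
        em = np.full((4, 3), -50.0)
        em[np.arange(4), y] = 50.0
        loss = nll_loss(em, y, CrfParameters.zeros(3))
        assert 0.0 <= loss < 1e-8

    def test_nonnegative(self, rng):
        for _ in range(20):
            em, p = random_crf_instance(rng, L=6, K=3)
            y = rng.integers(0, 3, size=6)
            assert nll_loss(em, y, p) >= -1e-12


def finite_difference_gradients(em, y, p, step=1e-5):
    """Central finite differences of the NLL in every parameter block."""
    def loss_at(em_, tr_, st_, sp_):
        return nll_loss(em_, y, CrfParameters(tr_, st_, sp_))

    blocks = {
        "emissions": em.copy(), "transitions": p.transitions.copy(),
        "start": p.start.copy(), "stop": p.stop.copy(),
    }
    grads = {}
    for name, arr in blocks.items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for sign in (+1, -1):
                perturbed = {k: v.copy() for k, v in blocks.items()}
                perturbed[name][idx] += sign * step
                val = loss_at(perturbed["emissions"], perturbed["transitions"],
                              perturbed["start"], perturbed["stop"])
                g[idx] += sign * val / (2 * step)
        grads[name] = g
    return grads


class TestGradients:
    def test_emission_gradient_is_marginals_minus_onehot(self, rng):
        em, p = random_crf_instance(rng, L=5, K=3)
        y = rng.integers(0, 3, size=5)
        _, unary, _ = forward_backward(em, p)
        onehot = np.zeros_like(em)
        onehot[np.arange(5), y] = 1.0
        _, d_em, *_ = nll_gradients(em, y, p)
        np.testing.assert_allclose(d_em, unary - onehot, atol=1e-12)

    @pytest.mark.parametrize("L,K", [(1, 3), (4, 2), (6, 3), (3, 5)])
    def test_matches_central_differences(self, rng, L, K):
        em, p = random_crf_instance(rng, L=L, K=K, scale=1.0)
        y = rng.integers(0, K, size=L)
        _, d_em, d_tr, d_st, d_sp = nll_gradients(em, y, p)
        fd = finite_difference_gradients(em, y, p)
        for analytic, name in [(d_em, "emissions"), (d_tr, "transitions"),
                               (d_st, "start"), (d_sp, "stop")]:
            denom = max(np.abs(fd[name]).max(), 1.0)
            assert np.abs(analytic - fd[name]).max() / denom < 1e-4, name

    def test_batched_loss_matches_per_sequence_mean(self, rng):
        K = 3
        lengths = np.array([4, 6, 3])
        L = lengths.max()
        em = rng.standard_normal((3, L, K))
        labels = rng.integers(0, K, size=(3, L))
        p = CrfParameters(rng.standard_normal((K, K)), rng.standard_normal(K),
                          rng.standard_normal(K))
        node = crf_nll_batch(
            Tensor(em, requires_grad=True), Tensor(p.transitions, requires_grad=True),
            Tensor(p.start, requires_grad=True), Tensor(p.stop, requires_grad=True),
            labels, lengths,
        )
        expected = np.mean([
            nll_loss(em[b, :Lb], labels[b, :Lb], p)
            for b, Lb in enumerate(lengths)
        ])
        assert node.item() == pytest.approx(expected, abs=1e-10)

    def test_batched_loss_backward_matches_analytic(self, rng):
        K, lengths = 2, np.array([3, 5])
        L = lengths.max()
        em_arr = rng.standard_normal((2, L, K))
        labels = rng.integers(0, K, size=(2, L))
        em = Tensor(em_arr, requires_grad=True)
        tr = Tensor(rng.standard_normal((K, K)), requires_grad=True)
        st = Tensor(np.zeros(K), requires_grad=True)
        sp = Tensor(np.zeros(K), requires_grad=True)
        node = crf_nll_batch(em, tr, st, sp, labels, lengths)
        node.backward()
        p = CrfParameters(tr.data, st.data, sp.data)
        expected_tr = np.zeros((K, K))
        for b, Lb in enumerate(lengths):
            _, d_em, d_tr, _, _ = nll_gradients(em_arr[b, :Lb], labels[b, :Lb], p)
            np.testing.assert_allclose(em.grad[b, :Lb], d_em / 2, atol=1e-12)
            assert np.allclose(em.grad[b, Lb:], 0.0)
            expected_tr += d_tr / 2
        np.testing.assert_allclose(tr.grad, expected_tr, atol=1e-12)
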