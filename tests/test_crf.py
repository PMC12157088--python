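"""Linear-chain CRF against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from lexner import nn
from lexner.crf import (CRFLayer, CRFParams, crf_log_partition, crf_nll,
                        crf_score, viterbi_decode)


def enumerate_scores(P, T):
    """Score of every label path, brute force."""
    n, L = P.shape
    return {Y: crf_score(P, T, list(Y))
            for Y in itertools.product(range(L), repeat=n)}


def random_instance(rng, n_max=6, L_max=5):
    n = int(rng.integers(1, n_max + 1))
    L = int(rng.integers(1, L_max + 1))
    return rng.normal(size=(n, L)) * 2, rng.normal(size=(L, L))


class TestScore:
    def test_single_position_is_pure_emission(self):
        assert crf_score([[1.5, -2.0]], np.zeros((2, 2)), [1]) == -2.0

    def test_hand_worked_two_step_path(self):
        P = np.array([[0.5, 1.0], [0.2, 0.3]])
        T = np.array([[0.1, 0.2], [0.3, 0.4]])
        # emissions 0.5 + 0.3, transition 0 -> 1 scores 0.2
        assert crf_score(P, T, [0, 1]) == pytest.approx(1.0)

    def test_concatenation_additivity(self, rng):
        P1, T = rng.normal(size=(3, 4)), rng.normal(size=(4, 4))
        P2 = rng.normal(size=(2, 4))
        Y1, Y2 = [0, 2, 1], [3, 3]
        joint = crf_score(np.vstack([P1, P2]), T, Y1 + Y2)
        assert joint == pytest.approx(crf_score(P1, T, Y1) + crf_score(P2, T, Y2)
                                      + T[Y1[-1], Y2[0]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            crf_score(np.zeros((2, 2)), np.zeros((2, 2)), [0, 5])


class TestPartition:
    def test_two_equal_paths_give_log2(self):
        assert crf_log_partition([[0.0, 0.0]], np.zeros((2, 2))) == pytest.approx(np.log(2))

    def test_single_label_collapses_to_path_score(self, rng):
        P = rng.normal(size=(4, 1))
        T = rng.normal(size=(1, 1))
        assert crf_log_partition(P, T) == pytest.approx(P.sum() + 3 * T[0, 0])

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(200):
            P, T = random_instance(rng)
            want = logsumexp(list(enumerate_scores(P, T).values()))
            assert crf_log_partition(P, T) == pytest.approx(want, abs=1e-6)

    def test_emission_shift_moves_logz_by_constant(self, rng):
        P, T = random_instance(rng, n_max=5, L_max=4)
        shifted = P.copy()
        shifted[0] += 3.7
        assert crf_log_partition(shifted, T) == pytest.approx(
            crf_log_partition(P, T) + 3.7, abs=1e-9)


class TestNLL:
    def test_single_label_inventory_has_zero_loss(self, rng):
        P = rng.normal(size=(5, 1))
        assert crf_nll(P, np.zeros((1, 1)), [0] * 5) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumerated_negative_log_probability(self, rng):
        for _ in range(50):
            P, T = random_instance(rng, n_max=5, L_max=4)
            scores = enumerate_scores(P, T)
            gold = tuple(int(rng.integers(P.shape[1])) for _ in range(P.shape[0]))
            prob = np.exp(scores[gold] - logsumexp(list(scores.values())))
            assert crf_nll(P, T, list(gold)) == pytest.approx(-np.log(prob), abs=1e-6)
            assert crf_nll(P, T, list(gold)) >= -1e-6

    def test_path_probabilities_normalize(self, rng):
        P, T = random_instance(rng, n_max=4, L_max=4)
        logZ = crf_log_partition(P, T)
        total = sum(np.exp(s - logZ) for s in enumerate_scores(P, T).values())
        assert total == pytest.approx(1.0, abs=1e-6)


class TestViterbi:
    def test_single_position_argmax(self):
        path, score = viterbi_decode([[0.1, 0.9, 0.3]], np.zeros((3, 3)))
        assert (path, score) == ([1], pytest.approx(0.9))

    def test_zero_transitions_reduce_to_positionwise_argmax(self, rng):
        P = rng.normal(size=(6, 4))
        path, _ = viterbi_decode(P, np.zeros((4, 4)))
        assert path == list(np.argmax(P, axis=1))

    def test_matches_enumeration_argmax(self, rng):
        for _ in range(200):
            P, T = random_instance(rng, n_max=6, L_max=5)
            scores = enumerate_scores(P, T)
            best = max(scores, key=scores.get)
            path, score = viterbi_decode(P, T)
            assert tuple(path) == best
            assert score == pytest.approx(scores[best], abs=1e-9)

    def test_viterbi_never_below_gold(self, rng):
        P, T = random_instance(rng, n_max=5, L_max=4)
        _, star = viterbi_decode(P, T)
        gold = [0] * P.shape[0]
        assert star >= crf_score(P, T, gold) - 1e-12


class TestCRFLayerTraining:
    def test_layer_nll_agrees_with_numpy_path(self, rng):
        layer = CRFLayer(4, ["O", "B-a", "I-a"], rng)
        h = rng.normal(size=(5, 4))
        em = layer.emissions(nn.Tensor(h))
        y = np.array([0, 1, 2, 2, 0])
        want = crf_nll(em.data, layer.transitions.data, y)
        assert layer.nll(em, y).item() == pytest.approx(want, abs=1e-9)

    def test_gradient_step_reduces_nll(self, rng):
        layer = CRFLayer(3, ["O", "B-a"], rng)
        h = nn.Tensor(rng.normal(size=(4, 3)))
        y = np.array([0, 1, 0, 1])
        opt = nn.Adam(layer.parameters(), lr=5e-2)
        before = layer.nll(layer.emissions(h), y).item()
        for _ in range(5):
            opt.zero_grad()
            loss = layer.nll(layer.emissions(h), y)
            loss.backward()
            opt.step()
        assert layer.nll(layer.emissions(h), y).item() < before

    def test_decode_is_deterministic(self, rng):
        layer = CRFLayer(3, ["O", "B-a", "I-a"], rng)
        em = rng.normal(size=(6, 3))
        assert layer.decode(em) == layer.decode(em)


class TestOptionalFlags:
    def test_zero_boundary_scores_change_nothing(self, rng):
        plain = CRFLayer(3, ["O", "B-a", "I-a"], rng)
        bounded = CRFLayer(3, ["O", "B-a", "I-a"], np.random.default_rng(0), boundary=True)
        bounded.emit.load_state_dict(plain.emit.state_dict())
        bounded.transitions.data = plain.transitions.data.copy()
        h = nn.Tensor(rng.normal(size=(4, 3)))
        y = np.array([0, 1, 2, 0])
        assert bounded.nll(bounded.emissions(h), y).item() == pytest.approx(
            plain.nll(plain.emissions(h), y).item(), abs=1e-12)
        assert bounded.decode(plain.emissions(h).data) == plain.decode(plain.emissions(h).data)

    def test_boundary_scores_shift_first_and_last_rows(self, rng):
        layer = CRFLayer(3, ["O", "B-a"], rng, boundary=True)
        layer.start.data[:] = [5.0, -5.0]
        layer.stop.data[:] = [-5.0, 5.0]
        em = np.zeros((3, 2))
        path, _ = layer.decode(em)
        assert path[0] == 0 and path[-1] == 1

    def test_boundary_gradients_flow(self, rng):
        layer = CRFLayer(2, ["O", "B-a"], rng, boundary=True)
        loss = layer.nll(layer.emissions(nn.Tensor(rng.normal(size=(3, 2)))),
                         np.array([0, 1, 0]))
        loss.backward()
        assert layer.start.grad is not None and np.abs(layer.start.grad).sum() > 0

    def test_scheme_constrained_decode_never_emits_dangling_i(self, rng):
        labels = ["O", "B-a", "I-a", "B-b", "I-b"]
        layer = CRFLayer(4, labels, rng, constrain_scheme=True)
        # emissions that strongly prefer I- tags everywhere
        em = np.full((6, 5), -1.0)
        em[:, [2, 4]] = 3.0
        path, _ = layer.decode(em)
        prev = None
        for idx in path:
            lab = labels[idx]
            if lab.startswith("I-"):
                assert prev in (f"B-{lab[2:]}", f"I-{lab[2:]}")
            prev = lab


def test_crfparams_validates_shape_and_finiteness():
    with pytest.raises(ValueError):
        CRFParams(["O", "B"], np.zeros((3, 3)))
    with pytest.raises(ValueError):
        CRFParams(["O"], np.array([[np.inf]]))
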