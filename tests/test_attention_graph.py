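"""Multi-head attention, entity-graph construction, adjacency normalisation,
and gated graph propagation, each against independent dense computations."""

import numpy as np
import pytest

from lexner import nn
from lexner.attention_graph import (GGNN, EntityGraph, MultiHeadAttention,
                                    build_entity_graph, normalize_adjacency)
from lexner.char_word_features import WordMatch


def np_softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def mha_oracle(x, mha):
    """Dense numpy re-implementation of the layer, head by head."""
    q, k, v = x @ mha.wq.W.data, x @ mha.wk.W.data, x @ mha.wv.W.data
    heads = []
    for i in range(mha.h):
        qi = q @ mha.head_q[i].W.data
        ki = k @ mha.head_k[i].W.data
        vi = v @ mha.head_v[i].W.data
        heads.append(np_softmax(qi @ ki.T / np.sqrt(mha.d_head)) @ vi)
    return np.concatenate(heads, axis=1) @ mha.wo.W.data + mha.wo.b.data


class TestMultiHeadAttention:
    def test_single_head_equals_direct_scaled_attention(self, rng):
        mha = MultiHeadAttention(4, 1, rng)
        x = rng.normal(size=(5, 4))
        np.testing.assert_allclose(mha(nn.Tensor(x)).data, mha_oracle(x, mha), atol=1e-10)

    def test_two_heads_match_by_hand_computation(self, rng):
        mha = MultiHeadAttention(4, 2, np.random.default_rng(1))
        x = rng.normal(size=(3, 4))
        np.testing.assert_allclose(mha(nn.Tensor(x)).data, mha_oracle(x, mha), atol=1e-6)

    @pytest.mark.parametrize("n,d,h", [(2, 4, 2), (7, 8, 4), (1, 6, 3)])
    def test_output_shape_preserved(self, rng, n, d, h):
        mha = MultiHeadAttention(d, h, rng)
        assert mha(nn.Tensor(rng.normal(size=(n, d)))).shape == (n, d)

    def test_head_weight_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(6, 3, rng)
        _, weights = mha(nn.Tensor(rng.normal(size=(5, 6))), return_weights=True)
        for w in weights:
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        mha = MultiHeadAttention(4, 2, rng)
        x = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        out = mha(nn.Tensor(x)).data
        out_perm = mha(nn.Tensor(x[perm])).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-9)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            MultiHeadAttention(6, 4, rng)


class TestEntityGraph:
    def test_single_char_no_words_is_self_loop(self):
        g = build_entity_graph(1, [])
        np.testing.assert_array_equal(g.A, [[1.0]])

    def test_hand_constructed_three_char_one_word(self):
        # chars 0-1-2 chained, word node 3 covers chars 1..2
        g = build_entity_graph(3, [WordMatch("xy", 1, 3, 0, 1)])
        want = np.array([
            [1, 1, 0, 0],
            [1, 1, 1, 1],
            [0, 1, 1, 1],
            [0, 1, 1, 1],
        ], dtype=float)
        np.testing.assert_array_equal(g.A, want)
        np.testing.assert_array_equal(g.D, np.diag(want.sum(axis=1)))

    def test_symmetry_for_random_match_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            matches = []
            for j in range(rng.integers(0, 4)):
                s = int(rng.integers(0, n))
                e = int(rng.integers(s + 1, n + 1))
                matches.append(WordMatch(f"w{j}", s, e, j, 1))
            g = build_entity_graph(n, matches)
            np.testing.assert_array_equal(g.A, g.A.T)
            assert (np.diag(g.A) == 1).all()

    def test_word_word_overlap_edges_optional(self):
        matches = [WordMatch("ab", 0, 2, 0, 1), WordMatch("bc", 1, 3, 1, 1)]
        plain = build_entity_graph(3, matches)
        linked = build_entity_graph(3, matches, word_word_edges=True)
        assert plain.A[3, 4] == 0 and linked.A[3, 4] == 1

    def test_out_of_range_span_rejected(self):
        with pytest.raises(ValueError):
            build_entity_graph(2, [WordMatch("abc", 1, 4, 0, 1)])


class TestNormalizeAdjacency:
    def test_identity_is_fixed_point(self):
        np.testing.assert_array_equal(normalize_adjacency(np.eye(3)), np.eye(3))

    def test_hand_two_node_clique(self):
        np.testing.assert_allclose(normalize_adjacency(np.ones((2, 2))),
                                   0.5 * np.ones((2, 2)))

    def test_matches_dense_matrix_product_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 13))
            A = (rng.random((k, k)) < 0.4).astype(float)
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 1.0)
            D_inv_sqrt = np.diag(1.0 / np.sqrt(A.sum(axis=1)))
            np.testing.assert_allclose(normalize_adjacency(A),
                                       D_inv_sqrt @ A @ D_inv_sqrt, atol=1e-8)

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 13))
            A = (rng.random((k, k)) < 0.5).astype(float)
            A = np.maximum(A, A.T)
            np.fill_diagonal(A, 1.0)
            radius = np.abs(np.linalg.eigvalsh(normalize_adjacency(A))).max()
            assert radius <= 1.0 + 1e-10

    def test_zero_degree_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.zeros((2, 2)))


def two_node_graph():
    A = np.ones((2, 2))
    return EntityGraph(A, np.diag(A.sum(axis=1)), normalize_adjacency(A))


class TestGGNN:
    def test_zero_rounds_is_identity(self, rng):
        ggnn = GGNN(4, 0, rng)
        h0 = nn.Tensor(rng.normal(size=(3, 4)))
        g = build_entity_graph(3, [])
        np.testing.assert_array_equal(ggnn(h0, g).data, h0.data)

    def test_closed_update_gate_freezes_state(self, rng):
        ggnn = GGNN(4, 3, rng)
        ggnn.bz.data[:] = -1e9  # sigmoid -> 0: keep history untouched
        h0 = nn.Tensor(rng.normal(size=(3, 4)))
        out = ggnn(h0, build_entity_graph(3, []))
        np.testing.assert_allclose(out.data, h0.data, atol=1e-12)

    def test_open_update_gate_takes_candidate(self, rng):
        ggnn = GGNN(3, 1, rng)
        ggnn.bz.data[:] = 1e9   # sigmoid -> 1: state becomes the candidate
        h0 = rng.normal(size=(2, 3))
        g = two_node_graph()
        out = ggnn(nn.Tensor(h0), g).data
        prop = g.A_norm @ h0 @ ggnn.Wg.data
        r = 1.0 / (1.0 + np.exp(-(prop @ ggnn.Wr.data + h0 @ ggnn.Ur.data)))
        cand = np.tanh(prop @ ggnn.Wh.data + r * (h0 @ ggnn.Uh.data))
        np.testing.assert_allclose(out, cand, atol=1e-9)

    def test_single_round_matches_hand_evaluation(self, rng):
        ggnn = GGNN(2, 1, np.random.default_rng(5))
        h0 = rng.normal(size=(2, 2))
        g = two_node_graph()
        out = ggnn(nn.Tensor(h0), g).data

        sig = lambda x: 1.0 / (1.0 + np.exp(-x))
        prop = g.A_norm @ h0 @ ggnn.Wg.data
        z = sig(prop @ ggnn.Wz.data + h0 @ ggnn.Uz.data + ggnn.bz.data)
        r = sig(prop @ ggnn.Wr.data + h0 @ ggnn.Ur.data + ggnn.br.data)
        cand = np.tanh(prop @ ggnn.Wh.data + r * (h0 @ ggnn.Uh.data) + ggnn.bh.data)
        want = (1 - z) * h0 + z * cand
        np.testing.assert_allclose(out, want, atol=1e-6)

    def test_ten_rounds_remain_finite(self, rng):
        ggnn = GGNN(6, 10, rng)
        matches = [WordMatch("ab", 0, 2, 0, 1), WordMatch("cd", 2, 4, 1, 2)]
        g = build_entity_graph(5, matches)
        out = ggnn(nn.Tensor(rng.normal(size=(7, 6)) * 3), g)
        assert np.isfinite(out.data).all()

    def test_node_count_mismatch_rejected(self, rng):
        ggnn = GGNN(4, 1, rng)
        with pytest.raises(ValueError):
            ggnn(nn.Tensor(rng.normal(size=(3, 4))), two_node_graph())

    def test_negative_rounds_rejected(self, rng):
        with pytest.raises(ValueError):
            GGNN(4, -1, rng)
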