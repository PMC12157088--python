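"""Multi-head self-attention and gated graph propagation over the fused
character+word sequence.

MHA refines the (n+m)×d cross-stream output with h parallel scaled
dot-product heads (shared Q/K/V projections followed by per-head subspace
projections, concatenation, and an output projection).

The graph stage models dependencies between characters and the lexicon
words covering them: nodes are the n characters plus the m matched words,
edges are the character chain, word↔covered-character links, self-loops,
and (optionally) word–word overlap links.  Node states are propagated T
rounds through the symmetrically normalised adjacency Ã = D^{-1/2} A D^{-1/2}
and updated with GRU-style update/reset gates, which keeps repeated
propagation contractive instead of blowing up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .char_word_features import WordMatch


# --------------------------------------------------------------------------
# multi-head attention
# --------------------------------------------------------------------------

class MultiHeadAttention(nn.Module):
    def __init__(self, d: int, h: int, rng: np.random.Generator):
        if h < 1 or d % h:
            raise ValueError(f"head count {h} must divide hidden size {d}")
        self.d, self.h = d, h
        self.d_head = d // h
        self.wq = nn.Linear(d, d, rng, bias=False)
        self.wk = nn.Linear(d, d, rng, bias=False)
        self.wv = nn.Linear(d, d, rng, bias=False)
        # per-head subspace projections d -> d_head
        self.head_q = [nn.Linear(d, self.d_head, rng, bias=False) for _ in range(h)]
        self.head_k = [nn.Linear(d, self.d_head, rng, bias=False) for _ in range(h)]
        self.head_v = [nn.Linear(d, self.d_head, rng, bias=False) for _ in range(h)]
        self.wo = nn.Linear(h * self.d_head, d, rng)

    def __call__(self, x: nn.Tensor, return_weights: bool = False):
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scale = float(np.sqrt(self.d_head))
        heads, weights = [], []
        for i in range(self.h):
            qi, ki, vi = self.head_q[i](q), self.head_k[i](k), self.head_v[i](v)
            w = ((qi @ ki.T) / scale).softmax(axis=-1)
            weights.append(w.data)
            heads.append(w @ vi)
        out = self.wo(nn.concat(heads, axis=1))
        return (out, weights) if return_weights else out


def multi_head_attention(h_prime: nn.Tensor, mha: MultiHeadAttention) -> nn.Tensor:
    return mha(h_prime)


# --------------------------------------------------------------------------
# entity graph
# --------------------------------------------------------------------------

@dataclass
class EntityGraph:
    A: np.ndarray        # binary symmetric adjacency with self-loops
    D: np.ndarray        # diagonal degree matrix
    A_norm: np.ndarray   # D^{-1/2} A D^{-1/2}

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalisation Ã = D^{-1/2} A D^{-1/2}."""
    A = np.asarray(A, dtype=np.float64)
    deg = A.sum(axis=1)
    if (deg <= 0).any():
        raise ValueError("zero-degree node; adjacency must include self-loops")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_entity_graph(n: int, matches: list[WordMatch],
                       word_word_edges: bool = False) -> EntityGraph:
    """Nodes 0..n-1 are characters (chained), nodes n..n+m-1 are matched
    words linked to every character they cover; all nodes get self-loops."""
    m = len(matches)
    A = np.eye(n + m)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    for j, match in enumerate(matches):
        if not (0 <= match.start < match.end <= n):
            raise ValueError(f"match span {match} outside [0, {n})")
        node = n + j
        for i in range(match.start, match.end):
            A[node, i] = A[i, node] = 1.0
    if word_word_edges:
        for j, a in enumerate(matches):
            for k in range(j + 1, m):
                b = matches[k]
                if a.start < b.end and b.start < a.end:
                    A[n + j, n + k] = A[n + k, n + j] = 1.0
    D = np.diag(A.sum(axis=1))
    return EntityGraph(A, D, normalize_adjacency(A))


# --------------------------------------------------------------------------
# gated graph propagation
# --------------------------------------------------------------------------

class GGNN(nn.Module):
    """T rounds of normalised-adjacency propagation with GRU gating.

    Round t:  H̃ = Ã H W_g;  Z = σ(H̃ W_z + H U_z + b_z);
    R = σ(H̃ W_r + H U_r + b_r);  Ĥ = tanh(H̃ W_h + R ⊙ (H U_h) + b_h);
    H ← (1−Z) ⊙ H + Z ⊙ Ĥ.  Gate biases start at zero.
    """

    def __init__(self, d: int, T: int, rng: np.random.Generator):
        if T < 0:
            raise ValueError("propagation rounds must be >= 0")
        self.d, self.T = d, T
        self.Wg = nn.Parameter(nn.xavier_uniform(rng, d, d))
        for name in ("Wz", "Uz", "Wr", "Ur", "Wh", "Uh"):
            setattr(self, name, nn.Parameter(nn.xavier_uniform(rng, d, d)))
        for name in ("bz", "br", "bh"):
            setattr(self, name, nn.Parameter(np.zeros(d)))

    def __call__(self, h0: nn.Tensor, graph: EntityGraph,
                 T: int | None = None) -> nn.Tensor:
        if h0.shape[0] != graph.n_nodes:
            raise ValueError(f"{h0.shape[0]} states for {graph.n_nodes} nodes")
        a_norm = nn.Tensor(graph.A_norm)
        h = h0
        for _ in range(self.T if T is None else T):
            prop = (a_norm @ h) @ self.Wg
            z = (prop @ self.Wz + h @ self.Uz + self.bz).sigmoid()
            r = (prop @ self.Wr + h @ self.Ur + self.br).sigmoid()
            cand = (prop @ self.Wh + r * (h @ self.Uh) + self.bh).tanh()
            h = (1.0 - z) * h + z * cand
        return h


def ggnn_propagate(h0: nn.Tensor, graph: EntityGraph, ggnn: GGNN,
                   T: int | None = None) -> nn.Tensor:
    return ggnn(h0, graph, T=T)
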