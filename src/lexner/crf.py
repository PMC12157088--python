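"""Linear-chain conditional random field.

A label path Y over emissions P (n×|L|) and transition scores T (|L|×|L|)
scores

    S(X, Y) = Σ_i P_i(y_i) + Σ_i T[y_i, y_{i+1}],

its probability is exp(S) normalised over all |L|^n paths, training
minimises the negative log-likelihood  logZ − S(gold), and decoding finds
the argmax path.  The partition function logZ is computed by the forward
algorithm in log space; decoding by the Viterbi dynamic program with a
deterministic tie-break (lowest label index, resolved from the last
position backwards).

Plain-numpy functions serve scoring and decoding; :class:`CRFLayer` wires
the same quantities into the autodiff graph for gradient training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from . import nn


@dataclass
class CRFParams:
    """Label inventory plus the scores CRF scoring needs."""
    labels: list[str]
    T_mat: np.ndarray  # |L| x |L|, T[i, j] scores label i -> label j

    label_index: dict[str, int] = field(init=False)

    def __post_init__(self):
        L = len(self.labels)
        if L < 1:
            raise ValueError("empty label inventory")
        self.T_mat = np.asarray(self.T_mat, dtype=np.float64)
        if self.T_mat.shape != (L, L):
            raise ValueError(f"transition matrix must be {L}x{L}")
        if not np.isfinite(self.T_mat).all():
            raise ValueError("non-finite transition scores")
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}


def _check(P: np.ndarray, T_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=np.float64)
    T_mat = np.asarray(T_mat, dtype=np.float64)
    if P.ndim != 2 or T_mat.shape != (P.shape[1], P.shape[1]):
        raise ValueError(f"shape mismatch: P {P.shape}, T {T_mat.shape}")
    if P.shape[0] < 1:
        raise ValueError("empty emission table")
    return P, T_mat


def crf_score(P: np.ndarray, T_mat: np.ndarray, Y: list[int] | np.ndarray) -> float:
    """Path score: emissions along Y plus transitions between neighbours."""
    P, T_mat = _check(P, T_mat)
    Y = np.asarray(Y, dtype=np.intp)
    if len(Y) != P.shape[0]:
        raise ValueError("label path length != sequence length")
    if Y.min() < 0 or Y.max() >= P.shape[1]:
        raise ValueError("label index out of range")
    s = float(P[np.arange(len(Y)), Y].sum())
    if len(Y) > 1:
        s += float(T_mat[Y[:-1], Y[1:]].sum())
    return s


def crf_log_partition(P: np.ndarray, T_mat: np.ndarray) -> float:
    """log Σ_Y exp(S(Y)) by the forward algorithm (log space)."""
    P, T_mat = _check(P, T_mat)
    alpha = P[0]
    for i in range(1, P.shape[0]):
        alpha = logsumexp(alpha[:, None] + T_mat, axis=0) + P[i]
    return float(logsumexp(alpha))


def crf_nll(P: np.ndarray, T_mat: np.ndarray, Y_gold) -> float:
    """Negative log-likelihood of the gold path: logZ − S(gold) ≥ 0."""
    return crf_log_partition(P, T_mat) - crf_score(P, T_mat, Y_gold)


def viterbi_decode(P: np.ndarray, T_mat: np.ndarray) -> tuple[list[int], float]:
    """Maximum-score path and its score.

    Ties are broken toward the lowest label index, resolved at the latest
    position first (argmax takes the first maximum during both the sweep
    and the final selection).
    """
    P, T_mat = _check(P, T_mat)
    n, L = P.shape
    delta = P[0]
    back = np.zeros((n, L), dtype=np.intp)
    for i in range(1, n):
        cand = delta[:, None] + T_mat          # cand[prev, cur]
        back[i] = np.argmax(cand, axis=0)      # first max -> lowest prev index
        delta = cand[back[i], np.arange(L)] + P[i]
    last = int(np.argmax(delta))
    path = [last]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i][path[-1]]))
    path.reverse()
    return path, float(delta[last])


def scheme_transition_mask(labels: list[str]) -> np.ndarray:
    """Boolean |L|×|L| matrix of BIO-legal transitions: I-x may only
    follow B-x or I-x."""
    L = len(labels)
    ok = np.ones((L, L), dtype=bool)
    for j, to in enumerate(labels):
        if to.startswith("I-"):
            cat = to[2:]
            for i, frm in enumerate(labels):
                ok[i, j] = frm in (f"B-{cat}", f"I-{cat}")
    return ok

#: finite stand-in for -inf so masked Viterbi stays NaN-free
_MASK_SCORE = -1e9


class CRFLayer(nn.Module):
    """Trainable emission projection + transition matrix.

    Emissions are an affine map of the per-character rows of the final
    feature representation; transitions are free parameters.  The loss is
    the exact sequence NLL via the differentiable forward algorithm.

    ``boundary=True`` adds zero-initialised trainable start/stop score
    vectors (equivalent to additive adjustments of the first and last
    emission rows); ``constrain_scheme=True`` masks BIO-illegal
    transitions during decoding only — training always uses the free
    transition matrix.
    """

    def __init__(self, d: int, labels: list[str], rng: np.random.Generator,
                 boundary: bool = False, constrain_scheme: bool = False):
        self.labels = list(labels)
        self.emit = nn.Linear(d, len(labels), rng)
        self.transitions = nn.Parameter(rng.uniform(-0.1, 0.1, size=(len(labels),) * 2))
        self.start = nn.Parameter(np.zeros(len(labels))) if boundary else None
        self.stop = nn.Parameter(np.zeros(len(labels))) if boundary else None
        self.constrain_scheme = constrain_scheme

    def emissions(self, h_char: nn.Tensor) -> nn.Tensor:
        """n×|L| emission scores from the n character rows of Hfinal."""
        return self.emit(h_char)

    def _with_boundary(self, emissions: nn.Tensor) -> nn.Tensor:
        if self.start is None:
            return emissions
        n = emissions.shape[0]
        pad = np.zeros((n, 1))
        pad[0, 0] = 1.0
        tail = np.zeros((n, 1))
        tail[-1, 0] = 1.0
        return (emissions + nn.Tensor(pad) @ self.start.reshape(1, -1)
                + nn.Tensor(tail) @ self.stop.reshape(1, -1))

    def nll(self, emissions: nn.Tensor, y_gold: np.ndarray) -> nn.Tensor:
        emissions = self._with_boundary(emissions)
        y = np.asarray(y_gold, dtype=np.intp)
        n = emissions.shape[0]
        gold = emissions[np.arange(n), y].sum()
        if n > 1:
            gold = gold + self.transitions[y[:-1], y[1:]].sum()
        alpha = emissions[0:1, :]                       # 1 x L
        for i in range(1, n):
            scores = alpha.reshape(-1, 1) + self.transitions
            alpha = scores.logsumexp(axis=0, keepdims=True) + emissions[i:i + 1, :]
        return alpha.logsumexp(axis=1).sum() - gold

    def decode(self, emissions: np.ndarray) -> tuple[list[int], float]:
        P = np.array(emissions, dtype=np.float64)
        if self.start is not None:
            P[0] += self.start.data
            P[-1] += self.stop.data
        T = self.transitions.data
        if self.constrain_scheme:
            T = np.where(scheme_transition_mask(self.labels), T, _MASK_SCORE)
            for j, lab in enumerate(self.labels):   # no dangling I- at the start
                if lab.startswith("I-"):
                    P[0, j] += _MASK_SCORE
        return viterbi_decode(P, T)

    def params(self) -> CRFParams:
        return CRFParams(self.labels, self.transitions.data.copy())
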