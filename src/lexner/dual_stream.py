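"""Dual-stream network and cross-stream attention (CSA).

The character stream (fed the fused n×2d char+word representation) and the
word stream (fed the m×d matched-word embeddings) are first transformed
independently to a common width d.  Cross-stream attention then lets each
stream query the other: character queries attend over word keys/values and
vice versa, with shared Wq/Wk/Wv projections and 1/√d scaling.  The output
stacks both attended streams into an (n+m)×d representation.

The word-to-character direction is printed ambiguously in some
formulations (queries taken from the character stream); the
``eq6_literal`` flag reproduces that literal reading — its output then has
n rows, one per character query — while the default uses word-stream
queries, the only reading that yields m word rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .char_word_features import FusedCharWord, WordFeatures


@dataclass
class CrossStreamOutput:
    Hc_prime: nn.Tensor            # n x d transformed char stream
    Hw_prime: nn.Tensor            # m x d transformed word stream
    Ac: nn.Tensor                  # n x d char stream after attending to words
    Aw: nn.Tensor                  # word stream after attending to chars
    H_prime: nn.Tensor             # [Ac; Aw], (n+m) x d in the default reading
    word_stream_empty: bool = False
    #: softmax weight matrices, for inspection/testing (None when m == 0)
    weights_c: np.ndarray | None = field(default=None, repr=False)
    weights_w: np.ndarray | None = field(default=None, repr=False)


class DualStreamNet(nn.Module):
    """Per-stream feature transforms plus the shared CSA projections."""

    def __init__(self, d: int, rng: np.random.Generator,
                 shared_qkv: bool = True, eq6_literal: bool = False):
        self.d = d
        self.eq6_literal = eq6_literal
        self.f_c = nn.Linear(2 * d, d, rng)
        self.f_w = nn.Linear(d, d, rng)
        self.wq = nn.Linear(d, d, rng, bias=False)
        self.wk = nn.Linear(d, d, rng, bias=False)
        self.wv = nn.Linear(d, d, rng, bias=False)
        if shared_qkv:
            self.wq2 = self.wk2 = self.wv2 = None
        else:
            self.wq2 = nn.Linear(d, d, rng, bias=False)
            self.wk2 = nn.Linear(d, d, rng, bias=False)
            self.wv2 = nn.Linear(d, d, rng, bias=False)

    # second-stream projections fall back to the shared ones
    def _proj2(self):
        if self.wq2 is None:
            return self.wq, self.wk, self.wv
        return self.wq2, self.wk2, self.wv2

    def transform_streams(self, fused: FusedCharWord,
                          wf: WordFeatures) -> tuple[nn.Tensor, nn.Tensor]:
        hc = self.f_c(fused.H).tanh()
        if wf.m == 0:
            return hc, nn.Tensor(np.zeros((0, self.d)))
        return hc, self.f_w(wf.Hw).tanh()

    def cross_stream_attention(self, hc_prime: nn.Tensor,
                               hw_prime: nn.Tensor) -> CrossStreamOutput:
        d = self.d
        if hc_prime.shape[1] != d or (hw_prime.shape[0] and hw_prime.shape[1] != d):
            raise ValueError("stream width mismatch")
        m = hw_prime.shape[0]
        if m == 0:
            # no lexicon matches: nothing to attend over, pass chars through
            return CrossStreamOutput(hc_prime, hw_prime, hc_prime, hw_prime,
                                     hc_prime, word_stream_empty=True)
        wq2, wk2, wv2 = self._proj2()
        scale = float(np.sqrt(d))
        qc, kw, vw = self.wq(hc_prime), wk2(hw_prime), wv2(hw_prime)
        weights_c = ((qc @ kw.T) / scale).softmax(axis=-1)
        ac = weights_c @ vw
        if self.eq6_literal:
            # literal reading: queries from the character stream attend over
            # character keys/values; rows align with characters, not words
            qw, kc, vc = self.wq(hc_prime), self.wk(hc_prime), self.wv(hc_prime)
        else:
            qw, kc, vc = wq2(hw_prime), self.wk(hc_prime), self.wv(hc_prime)
        weights_w = ((qw @ kc.T) / scale).softmax(axis=-1)
        aw = weights_w @ vc
        return CrossStreamOutput(hc_prime, hw_prime, ac, aw,
                                 nn.concat([ac, aw], axis=0),
                                 weights_c=weights_c.data, weights_w=weights_w.data)

    def __call__(self, fused: FusedCharWord, wf: WordFeatures) -> CrossStreamOutput:
        return self.cross_stream_attention(*self.transform_streams(fused, wf))


def transform_streams(fused: FusedCharWord, wf: WordFeatures,
                      net: DualStreamNet) -> tuple[nn.Tensor, nn.Tensor]:
    return net.transform_streams(fused, wf)


def cross_stream_attention(hc_prime: nn.Tensor, hw_prime: nn.Tensor,
                           net: DualStreamNet) -> CrossStreamOutput:
    return net.cross_stream_attention(hc_prime, hw_prime)
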