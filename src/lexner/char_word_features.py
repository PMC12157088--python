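"""Character-level and word-level feature extraction.

Two complementary views of a character-tokenised sentence:

* a contextual character encoder (small trainable transformer with fixed
  sinusoidal position codes) producing ``Hc`` of shape n×d, and
* SoftLexicon-style dictionary matching, which finds every multi-character
  substring present in a domain lexicon and embeds each matched word,
  producing ``Hw`` of shape m×d for m matches.

Because matched words cover variable spans, the word view is brought onto
the character grid by frequency-weighted pooling (each character receives
the mean of the embeddings of the words covering it, weighted by lexicon
frequency) before concatenation into the fused n×2d representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .data_io import LabeledSequence, Lexicon

UNK = "<unk>"

#: single characters are left to the character stream
MIN_MATCH_LEN = 2
DEFAULT_MAX_WORD_LEN = 8


@dataclass(frozen=True)
class WordMatch:
    """A lexicon word found at ``chars[start:end]``."""
    word: str
    start: int
    end: int
    embedding_index: int
    frequency: int


@dataclass
class CharFeatures:
    Hc: nn.Tensor  # n x d

    @property
    def n(self) -> int:
        return self.Hc.shape[0]


@dataclass
class WordFeatures:
    matches: list[WordMatch]
    Hw: nn.Tensor  # m x d

    @property
    def m(self) -> int:
        return len(self.matches)


@dataclass
class FusedCharWord:
    H: nn.Tensor  # n x 2d


def build_char_vocab(corpora, reserve: tuple[str, ...] = (UNK,)) -> dict[str, int]:
    """Index every character seen in the corpora, unknowns first."""
    vocab = {tok: i for i, tok in enumerate(reserve)}
    for corpus in corpora:
        for seq in corpus:
            for ch in seq.chars:
                vocab.setdefault(ch, len(vocab))
    return vocab


class CharEncoder(nn.Module):
    """Trainable transformer encoder over character embeddings.

    Depth-``depth`` pre-LN blocks with ``n_heads`` heads and a d→4d
    feed-forward; fixed sinusoidal position codes are added to the
    embeddings so identical characters at different positions encode
    differently.
    """

    def __init__(self, vocab: dict[str, int], d: int, depth: int,
                 rng: np.random.Generator, n_heads: int = 2):
        if d <= 0 or d % 2:
            raise ValueError("hidden dimension must be positive and even")
        if UNK not in vocab:
            raise ValueError(f"vocabulary must reserve {UNK!r}")
        self.vocab = dict(vocab)
        self.d = d
        self.embed = nn.Embedding(len(vocab), d, rng)
        self.blocks = [nn.TransformerBlock(d, n_heads, 4 * d, rng) for _ in range(depth)]
        self.ln_out = nn.LayerNorm(d)

    def indices(self, chars: list[str]) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(c, unk) for c in chars], dtype=np.intp)

    def __call__(self, chars: list[str]) -> CharFeatures:
        if len(chars) == 0:
            raise ValueError("empty sentence")
        h = self.embed(self.indices(chars)) + nn.sinusoidal_positions(len(chars), self.d)
        for block in self.blocks:
            h = block(h)
        return CharFeatures(self.ln_out(h))


def encode_characters(seq: LabeledSequence, encoder: CharEncoder) -> CharFeatures:
    return encoder(seq.chars)


def match_words(chars: list[str], lexicon: Lexicon,
                max_word_len: int = DEFAULT_MAX_WORD_LEN,
                word_index: dict[str, int] | None = None) -> list[WordMatch]:
    """All occurrences of lexicon words of length 2..max_word_len, sorted
    by (start, end).  ``word_index`` maps words to embedding rows; absent
    words map to row -1 (caller decides how to embed unknown words)."""
    if max_word_len < 1:
        raise ValueError("max_word_len must be >= 1")
    n = len(chars)
    text = "".join(chars)
    matches = []
    for start in range(n):
        for end in range(start + MIN_MATCH_LEN, min(start + max_word_len, n) + 1):
            word = text[start:end]
            if word in lexicon:
                idx = word_index.get(word, -1) if word_index is not None else -1
                matches.append(WordMatch(word, start, end, idx,
                                         lexicon.frequency(word)))
    return matches


class WordEmbedder(nn.Module):
    """Trainable embedding table over the lexicon vocabulary (+1 unknown row)."""

    def __init__(self, lexicon: Lexicon, d: int, rng: np.random.Generator):
        self.word_index = {w: i for i, w in enumerate(sorted(lexicon.words()))}
        self.d = d
        self.embed = nn.Embedding(len(self.word_index) + 1, d, rng)

    def __call__(self, matches: list[WordMatch]) -> WordFeatures:
        unk_row = len(self.word_index)
        rows = np.array([m.embedding_index if m.embedding_index >= 0 else unk_row
                         for m in matches], dtype=np.intp)
        if len(matches) == 0:
            return WordFeatures([], nn.Tensor(np.zeros((0, self.d))))
        return WordFeatures(list(matches), self.embed(rows))


def match_lexicon(seq: LabeledSequence, lexicon: Lexicon, embedder: WordEmbedder,
                  max_word_len: int = DEFAULT_MAX_WORD_LEN) -> WordFeatures:
    matches = match_words(seq.chars, lexicon, max_word_len, embedder.word_index)
    return embedder(matches)


def coverage_weights(n: int, matches: list[WordMatch]) -> np.ndarray:
    """n×m pooling matrix: entry (i, j) is freq_j normalised over the
    matches covering character i; zero rows where nothing matches."""
    m = len(matches)
    W = np.zeros((n, m))
    for j, match in enumerate(matches):
        W[match.start:match.end, j] = match.frequency
    totals = W.sum(axis=1, keepdims=True)
    np.divide(W, totals, out=W, where=totals > 0)
    return W


def pool_word_features_per_char(n: int, wf: WordFeatures, d: int) -> nn.Tensor:
    """Frequency-weighted mean of covering word embeddings per character."""
    if wf.m == 0:
        return nn.Tensor(np.zeros((n, d)))
    return nn.Tensor(coverage_weights(n, wf.matches)) @ wf.Hw


def fuse_char_word(cf: CharFeatures, pooled: nn.Tensor) -> FusedCharWord:
    """Concatenate the character view with the pooled word view: n×2d."""
    if cf.Hc.shape[0] != pooled.shape[0]:
        raise ValueError(f"row mismatch: {cf.Hc.shape[0]} chars vs {pooled.shape[0]} pooled")
    return FusedCharWord(nn.concat([cf.Hc, pooled], axis=1))
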