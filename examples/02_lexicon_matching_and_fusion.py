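"""Character/word feature extraction on one sentence.

Shows dictionary matching over a real Chinese example (including the
classic segmentation trap where a term's prefix is itself a dictionary
word), then the per-character pooling that aligns matched-word embeddings
with the character grid before fusion.
"""

import numpy as np

from lexner.char_word_features import (CharEncoder, WordEmbedder, UNK,
                                       fuse_char_word, match_lexicon,
                                       pool_word_features_per_char)
from lexner.data_io import LabeledSequence, Lexicon

lex = Lexicon()
lex.add("急性心肌梗死", 8, "disease")   # the full term ...
lex.add("急性心肌", 3, "disease")       # ... and a trap prefix
lex.add("心肌", 5, "body")

text = "患者急性心肌梗死入院"
seq = LabeledSequence(list(text), ["O"] * len(text))

rng = np.random.default_rng(0)
d = 8
embedder = WordEmbedder(lex, d, rng)
wf = match_lexicon(seq, lex, embedder)
print(f"text: {text}")
print(f"{wf.m} dictionary matches (note the overlapping trap prefix):")
for m in wf.matches:
    print(f"  [{m.start}:{m.end}] {m.word!r} freq={m.frequency}")

vocab = {UNK: 0, **{c: i + 1 for i, c in enumerate(dict.fromkeys(text))}}
encoder = CharEncoder(vocab, d, depth=2, rng=rng)
cf = encoder(seq.chars)
pooled = pool_word_features_per_char(seq.n, wf, d)
fused = fuse_char_word(cf, pooled)
print(f"\nHc: {cf.Hc.shape}, Hw: {wf.Hw.shape}, fused H: {fused.H.shape}")
covered = np.abs(pooled.data).sum(axis=1) > 0
print("characters covered by at least one matched word:",
      "".join(c for c, f in zip(text, covered) if f))
# Characters inside 急性心肌梗死 receive a frequency-weighted mean of the
# embeddings of every matched word covering them; the rest pool to zero.
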