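# lexner

Lexicon-enhanced named entity recognition for character-based text,
combining a dual-stream character/word architecture with cross-stream
attention, multi-head self-attention, gated graph propagation over a
character–word graph, and linear-chain CRF decoding.

## Why

In Chinese clinical text there are no word boundaries: a term like
急性心肌梗死 ("acute myocardial infarction") is easily fragmented by a
word segmenter, and a surface form like 发烧 can be a symptom in one
context but part of a disease name in another.  `lexner` avoids
segmentation entirely.  It tags at the character level and injects
dictionary evidence softly: every substring of the input that appears in
a domain lexicon becomes a matched word, and the model learns how much to
trust each match.

## The model

For a sentence of n characters with m lexicon matches:

1. **Character stream** — a trainable transformer encoder gives
   `Hc ∈ R^{n×d}`.
2. **Word stream** — matched words are embedded: `Hw ∈ R^{m×d}`;
   a frequency-weighted per-character pooling aligns them with the
   character grid, and concatenation gives the fused `H ∈ R^{n×2d}`.
3. **Dual streams + cross-stream attention** — after independent
   transforms, character queries attend over word keys/values and vice
   versa (scaled by 1/√d):
   `Ac = softmax(Qc Kwᵀ/√d) Vw`, `Aw = softmax(Qw Kcᵀ/√d) Vc`,
   stacked into `H' ∈ R^{(n+m)×d}`.
4. **Multi-head attention** — h scaled dot-product heads refine `H'`
   into `H''`.
5. **Graph propagation** — a per-sentence graph (character chain,
   word↔covered-character edges, self-loops) is normalised as
   `Ã = D^{-1/2} A D^{-1/2}` and node states are updated for T rounds
   with GRU-style update/reset gates.
6. **CRF** — emissions from the n character rows; training minimises the
   exact sequence NLL `logZ − S(gold)` via the log-space forward
   algorithm, decoding is Viterbi:
   `S(X,Y) = Σ_i P_i(y_i) + Σ_i T[y_i, y_{i+1}]`.

Evaluation is strict entity-level micro P/R/F1 (span and category must
both match).  Everything — including gradients — runs on numpy via a
small reverse-mode autodiff module; no deep-learning framework is
required.  See `docs/methods.md` for assumptions, defaults and
limitations.

Because real clinical corpora are not redistributable, the package ships
a synthetic-corpus generator that reproduces the phenomena the
architecture targets: multi-character dictionary entities, segmentation
traps (a word and its strict prefix both in the lexicon), and
category-ambiguous surface forms disambiguated by templated context.

## Worked example

`examples/04_train_and_evaluate.py` trains a reduced model (d = 32,
depth 1, ~36k parameters) on 800 synthetic sentences and scores the
held-out split:

```
model parameters: 35608
epoch 1: train NLL 21.398, dev F1 0.373
...
epoch 8: train NLL 3.496, dev F1 0.808

held-out report:
  "overall": {
    "TP": 188, "FP": 52, "FN": 32,
    "P": 0.7833, "R": 0.8545, "F1": 0.8174
  }
```

The NLL is the mean per-sentence negative log-likelihood of the gold
label path under the CRF; F1 counts a predicted entity only when its
span boundaries and category exactly match the annotation.  The full
benchmark configuration (d = 64, 2000 training sentences, 10 epochs)
reaches held-out F1 in the 0.92–0.96 range depending on the seed; the
other examples demonstrate corpus
generation, dictionary matching on the 急性心肌梗死 trap, exact CRF
inference versus enumeration, ablations and cross-validation.

A thin CLI wraps the same functions:

```sh
lexner simulate --seed 13 --out data/
lexner train --data data/ --checkpoint model.npz
lexner evaluate --checkpoint model.npz --data data/test.bio
lexner predict --checkpoint model.npz "某段文本"
lexner ablate --data data/ --seeds 0,1,2
lexner crossval --data data/ --k 5
```

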