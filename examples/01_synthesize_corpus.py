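"""Generate a small synthetic NER corpus and inspect what it contains.

Builds a lexicon of pseudo medical terms (with segmentation-trap prefixes
and category-ambiguous words), renders templated sentences with BIO
labels, and prints summary statistics.
"""

import numpy as np

from lexner import SynthConfig, generate_corpus, generate_lexicon
from lexner.synthetic_data import count_trap_pairs, is_ambiguous

cfg = SynthConfig(n_sentences=200, n_dev=40, n_test=40, lexicon_size=30,
                  entity_density=1.5, trap_rate=0.3, ambiguity_rate=0.3, seed=1)
lex = generate_lexicon(cfg)
corpus = generate_corpus(cfg, lex)

print(f"lexicon: {len(lex)} words, "
      f"{count_trap_pairs(lex)} trap pairs (word + strict prefix both listed), "
      f"{sum(is_ambiguous(cfg, w) for w in lex.words())} ambiguous surface forms")
counts = [len(s.spans()) for s in corpus.train]
print(f"train: {len(corpus.train)} sentences, "
      f"{np.mean(counts):.2f} entities/sentence on average")

sent = next(s for s in corpus.train if len(s.spans()) >= 2)
print("\nexample sentence:", sent.text)
for span in sent.spans():
    print(f"  [{span.start}:{span.end}] {sent.text[span.start:span.end]!r} "
          f"-> {span.category}")
# Each entity is a lexicon word; the characters flanking it are the
# category's context cue, which is what disambiguates ambiguous words.
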