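"""Train the full tagger on a small synthetic corpus and score it.

Uses a reduced corpus and model so the run finishes in well under a
minute; the standard benchmark in the acceptance script uses the full
2000-sentence configuration.
"""

import json

from lexner import SynthConfig, generate_corpus, generate_lexicon
from lexner import pipeline as pl

cfg = SynthConfig(n_sentences=800, n_dev=100, n_test=150, lexicon_size=30,
                  entity_density=1.5, seed=21)
lex = generate_lexicon(cfg)
corpus = generate_corpus(cfg, lex)
vocab = pl.build_char_vocab(corpus.splits().values())
cats = pl.corpus_categories(corpus.train)

model = pl.build_model(pl.ModelConfig(d=32, h=2, T_rounds=2, depth=1, seed=21),
                       lex, cats, vocab)
print(f"model parameters: {model.num_parameters()}")
result = pl.train(model, corpus.train, corpus.dev,
                  pl.TrainConfig(epochs=8, seed=21))
for rec in result.history:
    print(f"epoch {rec['epoch']}: train NLL {rec['train_loss']:.3f}, "
          f"dev F1 {rec['dev_f1']:.3f}")

report = pl.evaluate(model, corpus.test)
print("\nheld-out report:")
print(json.dumps(report.as_dict(), indent=2))
# P/R/F1 are strict entity-level rates: a prediction counts only when
# span boundaries and category both match the gold annotation.

ents = pl.predict(model, corpus.test[0].text)
print("\npredicted entities for one held-out sentence:", ents)
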