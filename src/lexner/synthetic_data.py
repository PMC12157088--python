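"""Reproducible synthetic corpora for lexicon-enhanced NER.

Real clinical corpora are not redistributable here, so the generator
builds sentences that exercise the phenomena a character/word fusion
tagger has to handle:

* **multi-character entities** drawn from a generated lexicon (length 2–6),
  so dictionary matching and boundary detection matter;
* **segmentation traps**: a configurable fraction of lexicon words also
  have a strict prefix present in the lexicon, so a matcher fires on both
  the whole word and its prefix and the model must pick the full span;
* **category-ambiguous surface forms**: a fraction of words belong to two
  categories and only the templated context around an occurrence decides
  which one is correct.

Sentences are carrier characters with entities spliced in; every inserted
entity is wrapped in a category-specific left/right context character (the
"template"), which is what disambiguates ambiguous words.  Carrier
characters are drawn from the alphabet minus the context characters, so
chance carrier substrings can still collide with lexicon words (a matcher
false positive the model must learn to ignore) while the context signal
stays clean.  Everything is a pure function of the config seed.
"""

from __future__ import annotations

import json
import string
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data_io import (LabeledSequence, Lexicon, write_bio_corpus, write_lexicon,
                      write_span_corpus)

CATEGORY_NAMES = ["disease", "symptom", "drug", "procedure", "body", "exam"]


@dataclass
class SynthConfig:
    n_sentences: int = 2000
    n_dev: int = 200
    n_test: int = 400
    char_vocab_size: int = 30
    n_categories: int = 3
    lexicon_size: int = 40
    entity_density: float = 1.5      # expected entities per sentence (Poisson)
    ambiguity_rate: float = 0.2
    trap_rate: float = 0.2
    min_len: int = 8                 # carrier characters, excluding entities
    max_len: int = 18
    min_word_len: int = 2
    max_word_len: int = 6
    seed: int = 0
    cjk: bool = False                # draw pseudo-characters from the CJK block

    def __post_init__(self):
        for name in ("ambiguity_rate", "trap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_sentences < 0 or self.lexicon_size < 0:
            raise ValueError("sizes must be >= 0")
        if self.lexicon_size and self.lexicon_size < self.n_categories:
            raise ValueError("lexicon smaller than the category inventory")
        if not 2 <= self.min_word_len <= self.max_word_len:
            raise ValueError("word length bounds invalid")
        if self.char_vocab_size < self.max_word_len + 2 * self.n_categories:
            raise ValueError("character vocabulary too small for words plus context cues")

    def categories(self) -> list[str]:
        base = CATEGORY_NAMES[:self.n_categories]
        base += [f"cat{i}" for i in range(len(base), self.n_categories)]
        return base


def alphabet(cfg: SynthConfig) -> list[str]:
    if cfg.cjk:
        return [chr(0x4E00 + i) for i in range(cfg.char_vocab_size)]
    pool = string.ascii_lowercase + string.digits + string.ascii_uppercase
    if cfg.char_vocab_size > len(pool):
        raise ValueError(f"synthetic alphabet capped at {len(pool)} characters")
    return list(pool[:cfg.char_vocab_size])


def context_cues(cfg: SynthConfig) -> dict[str, tuple[str, str]]:
    """Deterministic (left, right) context character per category."""
    rng = np.random.default_rng([cfg.seed, 3])
    chars = alphabet(cfg)
    picks = rng.choice(len(chars), size=2 * cfg.n_categories, replace=False)
    return {cat: (chars[picks[2 * i]], chars[picks[2 * i + 1]])
            for i, cat in enumerate(cfg.categories())}


def is_ambiguous(cfg: SynthConfig, word: str) -> bool:
    """Stable per-word coin flip at ambiguity_rate (independent of order)."""
    u = np.random.default_rng([cfg.seed, 2, zlib.crc32(word.encode())]).random()
    return u < cfg.ambiguity_rate


def second_category(cfg: SynthConfig, word: str, primary: str) -> str:
    cats = [c for c in cfg.categories() if c != primary]
    idx = np.random.default_rng([cfg.seed, 4, zlib.crc32(word.encode())]).integers(len(cats))
    return cats[idx]


def allowed_categories(cfg: SynthConfig, lex: Lexicon, word: str) -> list[str]:
    primary = lex.entries[word]["category"]
    if cfg.n_categories > 1 and is_ambiguous(cfg, word):
        return [primary, second_category(cfg, word, primary)]
    return [primary]


def generate_lexicon(cfg: SynthConfig) -> Lexicon:
    """Random multi-character pseudo-words partitioned over categories,
    with (word, strict-prefix) trap pairs injected at ``trap_rate``."""
    rng = np.random.default_rng([cfg.seed, 0])
    chars = alphabet(cfg)
    cats = cfg.categories()
    lex = Lexicon()
    target_traps = int(rng.binomial(cfg.lexicon_size, cfg.trap_rate)) \
        if cfg.lexicon_size else 0
    traps_made = 0

    def has_prefix(w: str) -> bool:
        return any(w[:k] in lex for k in range(cfg.min_word_len, len(w)))

    def fresh_word(min_len: int) -> str:
        for _ in range(200):
            length = int(rng.integers(min_len, cfg.max_word_len + 1))
            w = "".join(rng.choice(chars) for _ in range(length))
            if w not in lex:
                return w
        raise ValueError("character vocabulary too small to draw distinct words")

    def add(word: str) -> None:
        lex.add(word, frequency=int(rng.integers(1, 50)),
                category=cats[len(lex) % len(cats)])

    while len(lex) < cfg.lexicon_size:
        if traps_made < target_traps:
            # complete a trap pair: add a strict prefix of an existing word
            candidates = [w for w in lex.words()
                          if len(w) > cfg.min_word_len and not has_prefix(w)]
            placed = False
            for _ in range(50):
                if not candidates:
                    break
                base = candidates[int(rng.integers(len(candidates)))]
                cut = int(rng.integers(cfg.min_word_len, len(base)))
                if base[:cut] not in lex:
                    add(base[:cut])
                    traps_made += 1
                    placed = True
                    break
            if placed:
                continue
            # no usable base yet: seed one long enough to take a prefix later
            add(fresh_word(min(cfg.min_word_len + 1, cfg.max_word_len)))
        else:
            add(fresh_word(cfg.min_word_len))
    return lex


def count_trap_pairs(lex: Lexicon, min_word_len: int = 2) -> int:
    """Words whose strict prefix (length >= min_word_len) is also present."""
    return sum(1 for w in lex.words()
               if any(w[:k] in lex for k in range(min_word_len, len(w))))


@dataclass
class SplitCorpus:
    train: list[LabeledSequence]
    dev: list[LabeledSequence]
    test: list[LabeledSequence]

    def splits(self) -> dict[str, list[LabeledSequence]]:
        return {"train": self.train, "dev": self.dev, "test": self.test}


def _make_sentence(cfg: SynthConfig, lex: Lexicon, rng: np.random.Generator,
                   carrier: list[str], cues: dict[str, tuple[str, str]],
                   words: list[str]) -> LabeledSequence:
    length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
    body = [carrier[i] for i in rng.integers(len(carrier), size=length)]
    k = int(rng.poisson(cfg.entity_density)) if lex.entries else 0
    cut_points = sorted(rng.integers(0, length + 1, size=k))
    chars: list[str] = []
    labels: list[str] = []
    prev = 0
    for cut in cut_points:
        chars.extend(body[prev:cut])
        labels.extend("O" for _ in range(cut - prev))
        prev = cut
        word = words[int(rng.integers(len(words)))]
        cat_options = allowed_categories(cfg, lex, word)
        cat = cat_options[int(rng.integers(len(cat_options)))]
        left, right = cues[cat]
        chars.append(left)
        labels.append("O")
        chars.extend(word)
        labels.extend([f"B-{cat}"] + [f"I-{cat}"] * (len(word) - 1))
        chars.append(right)
        labels.append("O")
    chars.extend(body[prev:])
    labels.extend("O" for _ in range(length - prev))
    return LabeledSequence(chars, labels)


def generate_corpus(cfg: SynthConfig, lex: Lexicon) -> SplitCorpus:
    """Disjoint train/dev/test splits of templated sentences."""
    if cfg.entity_density > 0 and cfg.n_sentences + cfg.n_dev + cfg.n_test > 0 \
            and len(lex) == 0:
        raise ValueError("entity_density > 0 requires a non-empty lexicon")
    rng = np.random.default_rng([cfg.seed, 1])
    cues = context_cues(cfg)
    cue_chars = {c for pair in cues.values() for c in pair}
    carrier = [c for c in alphabet(cfg) if c not in cue_chars]
    words = sorted(lex.words())
    seen: set[str] = set()

    def batch(count: int) -> list[LabeledSequence]:
        out = []
        for _ in range(count):
            for _attempt in range(20):
                sent = _make_sentence(cfg, lex, rng, carrier, cues, words)
                if sent.n and sent.text not in seen:
                    break
            seen.add(sent.text)
            out.append(sent)
        return out

    return SplitCorpus(batch(cfg.n_sentences), batch(cfg.n_dev), batch(cfg.n_test))


def write_corpus(out_dir: str | Path, cfg: SynthConfig, lex: Lexicon,
                 corpus: SplitCorpus) -> None:
    """Emit BIO + JSON-lines files per split, the lexicon, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, sentences in corpus.splits().items():
        write_bio_corpus(out / f"{name}.bio", sentences)
        write_span_corpus(out / f"{name}.jsonl", sentences)
    write_lexicon(out / "lexicon.tsv", lex)
    (out / "manifest.json").write_text(
        json.dumps({"config": asdict(cfg), "sizes": {k: len(v) for k, v in
                                                     corpus.splits().items()}},
                   indent=2) + "\n", encoding="utf-8")


def kfold_split(corpus: list[LabeledSequence], k: int,
                seed: int) -> list[tuple[list[LabeledSequence], list[LabeledSequence]]]:
    """k disjoint folds (sizes differing by at most 1) as (train, val) pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    order = np.random.default_rng(seed).permutation(len(corpus))
    folds = np.array_split(order, k)
    pairs = []
    for i in range(k):
        val = [corpus[j] for j in folds[i]]
        train = [corpus[j] for f in (folds[:i] + folds[i + 1:]) for j in f]
        pairs.append((train, val))
    return pairs


def standard_benchmark(seed: int = 13) -> SynthConfig:
    """The reference synthetic benchmark used throughout the docs and the
    end-to-end checks: 2000/200/400 sentences, 3 categories, 40-word
    lexicon, 20% ambiguous surface forms, 20% segmentation traps."""
    return SynthConfig(n_sentences=2000, n_dev=200, n_test=400,
                       n_categories=3, lexicon_size=40,
                       ambiguity_rate=0.2, trap_rate=0.2, seed=seed)
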