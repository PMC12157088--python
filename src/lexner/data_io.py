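"""Corpus and lexicon I/O: CoNLL-style BIO files, JSON-lines span files,
plain-text lexicons, and conversion between span annotations and BIO tags.

Conventions: character tokens (no word segmentation), 0-based half-open
spans, BIO scheme where an entity is a maximal B–I run of one category.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")


class SchemeError(ValueError):
    """A label sequence violates the BIO scheme."""


class ParseError(ValueError):
    """A corpus or lexicon file is malformed."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open character span ``[start, end)`` with an entity category."""
    start: int
    end: int
    category: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class LabeledSequence:
    """A character sequence with aligned BIO labels."""
    chars: list[str]
    labels: list[str]

    def __post_init__(self):
        if len(self.chars) != len(self.labels):
            raise ValueError("chars and labels differ in length")
        validate_bio(self.labels)

    @property
    def n(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)

    def spans(self) -> list[EntitySpan]:
        return bio_to_spans(self.labels)


@dataclass
class Lexicon:
    """Domain word list with optional per-word frequency and category."""
    entries: dict[str, dict] = field(default_factory=dict)

    def add(self, word: str, frequency: int = 1, category: str | None = None) -> None:
        if len(word) < 1:
            raise ValueError("empty lexicon word")
        if frequency < 0:
            raise ValueError(f"negative frequency for {word!r}")
        if word in self.entries:
            raise ValueError(f"duplicate lexicon word: {word!r}")
        self.entries[word] = {"frequency": frequency, "category": category}

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def frequency(self, word: str) -> int:
        return self.entries[word]["frequency"]

    def words(self) -> list[str]:
        return list(self.entries)

    def max_word_length(self) -> int:
        return max((len(w) for w in self.entries), default=0)


# --------------------------------------------------------------------------
# BIO scheme <-> spans
# --------------------------------------------------------------------------

def validate_bio(labels: Iterable[str], lenient: bool = False) -> list[str]:
    """Check BIO validity; in lenient mode repair dangling I- tags to B-.

    Returns the (possibly repaired) label list.  An ``I-x`` is dangling when
    it follows ``O``, the sequence start, or a tag of another category.
    """
    out: list[str] = []
    prev_cat: str | None = None
    for i, lab in enumerate(labels):
        if not _TAG_RE.match(lab):
            raise SchemeError(f"invalid tag {lab!r} at position {i}")
        if lab.startswith("I-"):
            cat = lab[2:]
            if prev_cat != cat:
                if not lenient:
                    raise SchemeError(
                        f"dangling {lab!r} at position {i} (follows "
                        f"{'start' if not out else out[-1]!r})")
                lab = "B-" + cat
            prev_cat = cat
        elif lab.startswith("B-"):
            prev_cat = lab[2:]
        else:
            prev_cat = None
        out.append(lab)
    return out


def spans_to_bio(n: int, spans: Iterable[EntitySpan]) -> list[str]:
    """Render non-overlapping spans as a BIO label list of length ``n``."""
    labels = ["O"] * n
    last_end = -1
    for sp in sorted(spans):
        if sp.end > n:
            raise ValueError(f"span {sp} exceeds sequence length {n}")
        if sp.start < last_end:
            raise ValueError(f"overlapping span {sp}")
        last_end = sp.end
        labels[sp.start] = f"B-{sp.category}"
        for i in range(sp.start + 1, sp.end):
            labels[i] = f"I-{sp.category}"
    return labels


def bio_to_spans(labels: list[str], lenient: bool = False) -> list[EntitySpan]:
    """Extract maximal B–I runs as spans (inverse of :func:`spans_to_bio`)."""
    labels = validate_bio(labels, lenient=lenient)
    spans: list[EntitySpan] = []
    start, cat = None, None
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            if start is not None:
                spans.append(EntitySpan(start, i, cat))
            start, cat = i, lab[2:]
        elif lab == "O":
            if start is not None:
                spans.append(EntitySpan(start, i, cat))
            start, cat = None, None
        # I- continues the open run (validity guaranteed above)
    if start is not None:
        spans.append(EntitySpan(start, len(labels), cat))
    return spans


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def read_bio_corpus(path: str | Path, lenient: bool = False) -> list[LabeledSequence]:
    """Read a two-column (char, tag) file with blank-line sentence breaks."""
    sentences: list[LabeledSequence] = []
    chars: list[str] = []
    labels: list[str] = []

    def flush():
        if chars:
            sentences.append(LabeledSequence(chars[:], validate_bio(labels, lenient)))
            chars.clear()
            labels.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            chars.append(cols[0])
            labels.append(cols[1])
    flush()
    return sentences


def write_bio_corpus(path: str | Path, sentences: Iterable[LabeledSequence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for ch, lab in zip(sent.chars, sent.labels):
                fh.write(f"{ch}\t{lab}\n")
            fh.write("\n")


def read_span_corpus(path: str | Path) -> list[LabeledSequence]:
    """Read JSON-lines records ``{"text":…, "entities":[{start,end,type}…]}``."""
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: bad JSON ({exc})") from exc
            chars = list(rec["text"])
            spans = [EntitySpan(e["start"], e["end"], e["type"])
                     for e in rec.get("entities", [])]
            sentences.append(LabeledSequence(chars, spans_to_bio(len(chars), spans)))
    return sentences


def write_span_corpus(path: str | Path, sentences: Iterable[LabeledSequence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            rec = {"text": sent.text,
                   "entities": [{"start": s.start, "end": s.end, "type": s.category}
                                for s in sent.spans()]}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def load_lexicon(path: str | Path) -> Lexicon:
    """Read ``word[TAB frequency[TAB category]]`` lines; frequency defaults to 1."""
    lex = Lexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            word = cols[0]
            try:
                freq = int(cols[1]) if len(cols) > 1 and cols[1] else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad frequency {cols[1]!r}") from exc
            cat = cols[2] if len(cols) > 2 and cols[2] else None
            try:
                lex.add(word, freq, cat)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return lex


def write_lexicon(path: str | Path, lex: Lexicon) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word, rec in lex.entries.items():
            cat = rec["category"] or ""
            fh.write(f"{word}\t{rec['frequency']}\t{cat}".rstrip("\t") + "\n")
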