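"""Entity-level evaluation: strict span matching, micro and per-category P/R/F1.

A predicted entity counts as a true positive only when an identical
(start, end, category) span exists in the gold annotation of the same
sentence.  Rates use the zero-denominator convention rate = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .data_io import EntitySpan


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def merge(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)

    def as_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "FN": self.FN,
                "P": self.precision, "R": self.recall, "F1": self.f1}


@dataclass
class EvalReport:
    overall: EvalCounts = field(default_factory=EvalCounts)
    per_category: dict[str, EvalCounts] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"overall": self.overall.as_dict(),
                "per_category": {c: v.as_dict() for c, v in sorted(self.per_category.items())}}


def evaluate_entities(gold: Sequence[Iterable[EntitySpan]],
                      pred: Sequence[Iterable[EntitySpan]]) -> EvalReport:
    """Micro-averaged exact-match span evaluation over parallel sentence lists."""
    if len(gold) != len(pred):
        raise ValueError(f"sentence count mismatch: {len(gold)} gold vs {len(pred)} pred")
    report = EvalReport()

    def cat_counts(cat: str) -> EvalCounts:
        return report.per_category.setdefault(cat, EvalCounts())

    for gold_sent, pred_sent in zip(gold, pred):
        g = set(gold_sent)
        p = set(pred_sent)
        for span in p & g:
            report.overall.TP += 1
            cat_counts(span.category).TP += 1
        for span in p - g:
            report.overall.FP += 1
            cat_counts(span.category).FP += 1
        for span in g - p:
            report.overall.FN += 1
            cat_counts(span.category).FN += 1
    return report
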