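"""End-to-end tagger: model assembly, training, evaluation, prediction.

The full architecture per sentence:

1. character encoder → Hc (n×d); lexicon matching + word embeddings → Hw (m×d)
2. per-character pooling and concatenation → fused H (n×2d)
3. dual-stream transforms + cross-stream attention → H′ ((n+m)×d)
4. multi-head self-attention → H″
5. gated graph propagation over the character/word graph → Hfinal
6. affine emissions from the n character rows, linear-chain CRF loss/decoding

Ablation flags reroute the pipeline: without the dual streams the fused
representation is projected to width d and stacked with the raw word
embeddings; without MHA the cross-stream output feeds the graph directly;
without the graph stage H″ feeds the emissions.  All variants share the
same CRF decoding contract.

Sentences are processed individually; a training step accumulates
gradients over a mini-batch of sentences before one optimiser update,
which is equivalent to padded batching without any masking machinery.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention_graph import GGNN, MultiHeadAttention, build_entity_graph
from .char_word_features import (CharEncoder, WordEmbedder, WordMatch,
                                 build_char_vocab, fuse_char_word, match_words,
                                 pool_word_features_per_char)
from .crf import CRFLayer
from .data_io import LabeledSequence, Lexicon, bio_to_spans
from .dual_stream import DualStreamNet
from .metrics import EvalReport, evaluate_entities
from .synthetic_data import SplitCorpus


@dataclass
class ModelConfig:
    d: int = 64
    h: int = 2                      # MHA heads
    T_rounds: int = 2               # graph propagation rounds
    depth: int = 2                  # encoder transformer blocks
    encoder_heads: int = 2
    max_word_len: int = 8
    dropout: float = 0.0
    use_dsn_csa: bool = True
    use_mha: bool = True
    use_ggnn: bool = True
    eq6_literal: bool = False
    residual: bool = False          # Hfinal = H'' + graph output
    word_word_edges: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.d <= 0 or self.d % self.h:
            raise ValueError(f"hidden size {self.d} must be positive and divisible by h={self.h}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.eq6_literal and not self.use_dsn_csa:
            raise ValueError("eq6_literal only applies when the dual streams are enabled")


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    lr: float = 1e-3
    grad_clip: float = 5.0
    patience: int = 0               # 0 disables early stopping on stalled dev F1
    early_stop_f1: float = 1.1      # stop once dev F1 reaches this (>1 disables)
    seed: int = 0
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.lr <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")


def label_inventory(categories: list[str]) -> list[str]:
    labels = ["O"]
    for cat in sorted(categories):
        labels += [f"B-{cat}", f"I-{cat}"]
    return labels


def corpus_categories(sentences: list[LabeledSequence]) -> list[str]:
    return sorted({lab[2:] for s in sentences for lab in s.labels if lab != "O"})


class TaggerModel(nn.Module):
    def __init__(self, cfg: ModelConfig, lexicon: Lexicon, labels: list[str],
                 vocab: dict[str, int]):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.lexicon = lexicon
        self.labels = list(labels)
        self.label_index = {lab: i for i, lab in enumerate(labels)}
        d = cfg.d
        self.encoder = CharEncoder(vocab, d, cfg.depth, rng, n_heads=cfg.encoder_heads)
        self.word_embedder = WordEmbedder(lexicon, d, rng)
        self.dual = DualStreamNet(d, rng, eq6_literal=cfg.eq6_literal) \
            if cfg.use_dsn_csa else None
        # ablation 1 replaces the dual streams with a plain width projection
        self.fuse_proj = None if cfg.use_dsn_csa else nn.Linear(2 * d, d, rng)
        self.mha = MultiHeadAttention(d, cfg.h, rng) if cfg.use_mha else None
        self.ggnn = GGNN(d, cfg.T_rounds, rng) if cfg.use_ggnn else None
        self.crf = CRFLayer(d, labels, rng)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)
        self.training = False

    # -- forward ------------------------------------------------------------

    def _dropout(self, x: nn.Tensor) -> nn.Tensor:
        p = self.cfg.dropout
        if not self.training or p <= 0.0:
            return x
        mask = (self._drop_rng.random(x.shape) >= p) / (1.0 - p)
        return x * nn.Tensor(mask)

    def forward(self, seq: LabeledSequence) -> tuple[nn.Tensor, dict]:
        """Emission table (n×|L|) plus intermediate representations."""
        cfg = self.cfg
        n = seq.n
        cf = self.encoder(seq.chars)
        matches = match_words(seq.chars, self.lexicon, cfg.max_word_len,
                              self.word_embedder.word_index)
        wf = self.word_embedder(matches)
        pooled = pool_word_features_per_char(n, wf, cfg.d)
        fused = fuse_char_word(cf, pooled)
        aux: dict = {"matches": matches, "n": n, "m": wf.m}

        if self.dual is not None:
            cso = self.dual(fused, wf)
            h = self._dropout(cso.H_prime)
            aux["cross_stream"] = cso
            word_rows = 0 if cso.word_stream_empty else cso.Aw.shape[0]
        else:
            h = self._dropout(self.fuse_proj(fused.H).tanh())
            if wf.m:
                h = nn.concat([h, wf.Hw], axis=0)
            word_rows = wf.m

        if self.mha is not None:
            h = self._dropout(self.mha(h))
        aux["H_doubleprime"] = h

        if self.ggnn is not None:
            # literal CSA yields char-aligned extra rows; map row j to char j
            if word_rows == len(matches):
                cover = matches
            else:
                cover = [WordMatch("", j, j + 1, -1, 1) for j in range(word_rows)]
            graph = build_entity_graph(n, cover, word_word_edges=cfg.word_word_edges)
            g = self.ggnn(h, graph)
            h = h + g if cfg.residual else g
        aux["H_final"] = h

        emissions = self.crf.emissions(h[:n, :])
        return emissions, aux

    # -- losses & decoding --------------------------------------------------

    def gold_indices(self, seq: LabeledSequence) -> np.ndarray:
        return np.array([self.label_index[lab] for lab in seq.labels], dtype=np.intp)

    def loss(self, seq: LabeledSequence) -> nn.Tensor:
        emissions, _ = self.forward(seq)
        return self.crf.nll(emissions, self.gold_indices(seq))

    def decode(self, seq: LabeledSequence) -> list[str]:
        with nn.no_grad():
            emissions, _ = self.forward(seq)
        path, _ = self.crf.decode(emissions.data)
        return [self.labels[i] for i in path]


def build_model(cfg: ModelConfig, lexicon: Lexicon, categories: list[str],
                vocab: dict[str, int]) -> TaggerModel:
    return TaggerModel(cfg, lexicon, label_inventory(categories), vocab)


# --------------------------------------------------------------------------
# training / evaluation / prediction
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)
    best_dev_f1: float = 0.0
    best_state: dict | None = None


def evaluate(model: TaggerModel, sentences: list[LabeledSequence]) -> EvalReport:
    gold = [s.spans() for s in sentences]
    pred = [bio_to_spans(model.decode(s), lenient=True) for s in sentences]
    return evaluate_entities(gold, pred)


def train(model: TaggerModel, train_set: list[LabeledSequence],
          dev_set: list[LabeledSequence], tc: TrainConfig) -> TrainResult:
    """Minimise the mean sequence NLL; track dev entity-F1 per epoch and
    keep the best-dev parameter state."""
    if not train_set:
        raise ValueError("empty training split")
    params = model.parameters()
    opt = nn.Adam(params, lr=tc.lr)
    order_rng = np.random.default_rng(tc.seed)
    result = TrainResult(best_dev_f1=-1.0, best_state=model.state_dict())
    stale = 0

    for epoch in range(1, tc.epochs + 1):
        model.training = True
        order = order_rng.permutation(len(train_set))
        total_loss = 0.0
        pending = 0
        opt.zero_grad()
        for pos, idx in enumerate(order):
            seq = train_set[idx]
            if seq.n == 0:
                continue
            loss = model.loss(seq)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"sentence {idx}")
            total_loss += value
            loss.backward(np.asarray(1.0 / tc.batch_size))
            pending += 1
            if pending == tc.batch_size or pos == len(order) - 1:
                nn.clip_grad_norm(params, tc.grad_clip)
                opt.step()
                opt.zero_grad()
                pending = 0
        model.training = False
        mean_loss = total_loss / len(train_set)
        dev_f1 = evaluate(model, dev_set).overall.f1 if dev_set else float("nan")
        record = {"epoch": epoch, "train_loss": mean_loss, "dev_f1": dev_f1}
        result.history.append(record)
        if tc.log_path:
            with open(tc.log_path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record) + "\n")
        if dev_set:
            if dev_f1 > result.best_dev_f1:
                result.best_dev_f1 = dev_f1
                result.best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
            if dev_f1 >= tc.early_stop_f1:
                break
            if tc.patience and stale >= tc.patience:
                break
        else:
            result.best_state = model.state_dict()

    model.load_state_dict(result.best_state)
    if tc.checkpoint_path:
        save_checkpoint(tc.checkpoint_path, model)
    return result


def predict(model: TaggerModel, text: str) -> list[dict]:
    """Entity spans (start/end/type/surface) for raw text."""
    if not text:
        raise ValueError("empty input text")
    seq = LabeledSequence(list(text), ["O"] * len(text))
    labels = model.decode(seq)
    return [{"start": s.start, "end": s.end, "type": s.category,
             "surface": text[s.start:s.end]}
            for s in bio_to_spans(labels, lenient=True)]


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def lexicon_hash(lex: Lexicon) -> str:
    payload = json.dumps(sorted((w, r["frequency"], r["category"] or "")
                                for w, r in lex.entries.items()))
    return format(zlib.crc32(payload.encode()), "08x")


def save_checkpoint(path: str | Path, model: TaggerModel) -> None:
    meta = {
        "config": asdict(model.cfg),
        "labels": model.labels,
        "vocab": model.encoder.vocab,
        "lexicon": {w: [r["frequency"], r["category"]]
                    for w, r in model.lexicon.entries.items()},
        "lexicon_hash": lexicon_hash(model.lexicon),
    }
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> TaggerModel:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k[len("param:"):]: archive[k] for k in archive.files
                 if k.startswith("param:")}
    lex = Lexicon()
    for word, (freq, cat) in meta["lexicon"].items():
        lex.add(word, freq, cat)
    cfg = ModelConfig(**meta["config"])
    model = TaggerModel(cfg, lex, meta["labels"], meta["vocab"])
    model.load_state_dict(state)
    return model


# --------------------------------------------------------------------------
# ablation suite & cross-validation
# --------------------------------------------------------------------------

ABLATION_VARIANTS = {
    "full": {},
    "no_dsn_csa": {"use_dsn_csa": False},
    "no_mha": {"use_mha": False},
    "no_ggnn": {"use_ggnn": False},
}


def run_ablation_suite(base_cfg: ModelConfig, corpus: SplitCorpus,
                       categories: list[str], vocab: dict[str, int],
                       lexicon: Lexicon, tc: TrainConfig,
                       seeds: list[int],
                       variants: list[str] | None = None) -> list[dict]:
    """Train each architecture variant per seed; return per-run P/R/F1 rows."""
    if not seeds:
        raise ValueError("at least one seed required")
    rows = []
    for name in (variants or list(ABLATION_VARIANTS)):
        overrides = ABLATION_VARIANTS[name]
        for seed in seeds:
            cfg = ModelConfig(**{**asdict(base_cfg), **overrides, "seed": seed})
            model = build_model(cfg, lexicon, categories, vocab)
            run_tc = TrainConfig(**{**asdict(tc), "seed": seed,
                                    "checkpoint_path": None, "log_path": None})
            train(model, corpus.train, corpus.dev, run_tc)
            counts = evaluate(model, corpus.test).overall
            rows.append({"variant": name, "seed": seed,
                         "P": counts.precision, "R": counts.recall,
                         "F1": counts.f1, "n_params": model.num_parameters()})
    return rows


def summarize_ablation(rows: list[dict]) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for name in {r["variant"] for r in rows}:
        sel = [r for r in rows if r["variant"] == name]
        out[name] = {
            metric: {"mean": float(np.mean([r[metric] for r in sel])),
                     "sd": float(np.std([r[metric] for r in sel]))}
            for metric in ("P", "R", "F1")
        }
        out[name]["n_params"] = sel[0]["n_params"]
    return out


def cross_validate(cfg: ModelConfig, sentences: list[LabeledSequence],
                   lexicon: Lexicon, k: int, tc: TrainConfig,
                   seed: int = 0) -> list[dict]:
    from .synthetic_data import kfold_split

    vocab = build_char_vocab([sentences])
    categories = corpus_categories(sentences)
    results = []
    for fold, (train_set, val_set) in enumerate(kfold_split(sentences, k, seed)):
        model = build_model(cfg, lexicon, categories, vocab)
        train(model, train_set, val_set, tc)
        counts = evaluate(model, val_set).overall
        results.append({"fold": fold, "P": counts.precision,
                        "R": counts.recall, "F1": counts.f1})
    return results
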