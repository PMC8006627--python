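"""Token-level evaluation: per-category metrics and the global
de-identification metric.

Two layers of accounting coexist:

* **Per category** — a token counts as a true positive for category X only
  when both gold and prediction assign X (B/I prefixes are ignored).
* **Binary (global de-identification)** — a token is *identifying* iff its
  category is one of NAME, DIR, LOC, NUM, FECHA, INST.  Section headers
  (CAB) are intentionally preserved in de-identified output, so they are
  non-identifying, like O.  A gold NAME token predicted FECHA is a category
  error but a binary true positive: it still gets removed from the text.
  The binary recall is the headline number of a de-identification system —
  the fraction of sensitive tokens that do not leak.

Micro-averaging: counts are pooled over documents before computing
precision/recall/F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .corpus_io import (
    AnnotatedDocument,
    ENTITY_LABELS,
    IDENTIFYING_LABELS,
    TaggedSequence,
    spans_to_bio,
)
from .errors import AlignmentError

__all__ = [
    "ConfusionCounts",
    "PRF",
    "EvalReport",
    "token_confusion",
    "strict_span_confusion",
    "prf",
    "global_deid",
    "evaluate_corpus",
    "evaluate_pairs",
]

_IDENT = frozenset(IDENTIFYING_LABELS)


def _category(tag: str) -> str:
    return tag[2:] if tag.startswith(("B-", "I-")) else tag


@dataclass
class ConfusionCounts:
    """Pooled TP/FP/FN per category plus the binary identifying layer."""

    per_category: dict[str, list[int]] = field(
        default_factory=lambda: {lab: [0, 0, 0] for lab in ENTITY_LABELS}
    )
    binary: list[int] = field(default_factory=lambda: [0, 0, 0])

    def merge(self, other: "ConfusionCounts") -> "ConfusionCounts":
        for lab, (tp, fp, fn) in other.per_category.items():
            acc = self.per_category.setdefault(lab, [0, 0, 0])
            acc[0] += tp
            acc[1] += fp
            acc[2] += fn
        for i in range(3):
            self.binary[i] += other.binary[i]
        return self


class PRF(NamedTuple):
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def prf(tp: int, fp: int, fn: int) -> PRF:
    """Precision, recall and F1 from pooled counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = 2PR/(P+R).
    A zero denominator yields 0 for the affected metric and sets the
    ``degenerate`` flag.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PRF(precision, recall, f1, degenerate)


def token_confusion(gold: TaggedSequence, pred: TaggedSequence) -> ConfusionCounts:
    """Token-level confusion counts between a gold and a predicted tagging.

    Both sequences must be over the same tokens.
    """
    if len(gold.tokens) != len(pred.tokens) or any(
        g.text != p.text for g, p in zip(gold.tokens, pred.tokens)
    ):
        raise AlignmentError("gold and predicted token sequences differ")
    counts = ConfusionCounts()
    for g_tag, p_tag in zip(gold.tags, pred.tags):
        g, p = _category(g_tag), _category(p_tag)
        if g == p and g != "O":
            counts.per_category[g][0] += 1
        else:
            if p != "O":
                counts.per_category[p][1] += 1
            if g != "O":
                counts.per_category[g][2] += 1
        g_id, p_id = g in _IDENT, p in _IDENT
        if g_id and p_id:
            counts.binary[0] += 1
        elif p_id:
            counts.binary[1] += 1
        elif g_id:
            counts.binary[2] += 1
    return counts


def global_deid(gold: TaggedSequence, pred: TaggedSequence) -> PRF:
    """The global de-identification metric: PRF over the binary
    identifying-vs-not layer, crediting detections regardless of category."""
    counts = token_confusion(gold, pred)
    return prf(*counts.binary)


def strict_span_confusion(gold_spans, pred_spans) -> ConfusionCounts:
    """Secondary, entity-level strict-match accounting.

    A predicted span is a true positive only when label, start and end all
    match a gold span exactly; everything else is a per-span FP/FN.  This is
    stricter than the primary token-level metrics (a one-token boundary slip
    costs a whole entity) and is provided as a clearly separate mode.  The
    binary layer counts spans with identifying labels the same way.
    """
    counts = ConfusionCounts()
    gold = {(s.start, s.end, s.label) for s in gold_spans}
    pred = {(s.start, s.end, s.label) for s in pred_spans}
    for start, end, label in gold & pred:
        counts.per_category[label][0] += 1
        if label in _IDENT:
            counts.binary[0] += 1
    for start, end, label in pred - gold:
        counts.per_category[label][1] += 1
        if label in _IDENT:
            counts.binary[1] += 1
    for start, end, label in gold - pred:
        counts.per_category[label][2] += 1
        if label in _IDENT:
            counts.binary[2] += 1
    return counts


_ROW_ORDER = list(ENTITY_LABELS) + ["global"]


@dataclass
class EvalReport:
    """Per-category and global metrics with their underlying counts."""

    counts: ConfusionCounts

    @property
    def per_category(self) -> dict[str, PRF]:
        return {
            lab: prf(*self.counts.per_category[lab]) for lab in ENTITY_LABELS
        }

    @property
    def global_metrics(self) -> PRF:
        return prf(*self.counts.binary)

    def to_dict(self) -> dict:
        out = {}
        for lab in ENTITY_LABELS:
            tp, fp, fn = self.counts.per_category[lab]
            p = prf(tp, fp, fn)
            out[lab] = {
                "tp": tp, "fp": fp, "fn": fn,
                "precision": p.precision, "recall": p.recall, "f1": p.f1,
            }
        tp, fp, fn = self.counts.binary
        g = self.global_metrics
        out["global"] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": g.precision, "recall": g.recall, "f1": g.f1,
        }
        return out

    def render(self) -> str:
        """Delimited text table: one row per category plus a global row."""
        lines = ["entity\tprecision\trecall\tf1\ttp\tfp\tfn"]
        d = self.to_dict()
        for lab in _ROW_ORDER:
            row = d[lab]
            lines.append(
                f"{lab}\t{row['precision']:.4f}\t{row['recall']:.4f}\t"
                f"{row['f1']:.4f}\t{row['tp']}\t{row['fp']}\t{row['fn']}"
            )
        return "\n".join(lines)


def evaluate_pairs(
    pairs: Iterable[tuple[TaggedSequence, TaggedSequence]],
) -> EvalReport:
    """Micro-averaged report over (gold, predicted) tagged-sequence pairs."""
    total = ConfusionCounts()
    for gold, pred in pairs:
        total.merge(token_confusion(gold, pred))
    return EvalReport(total)


def evaluate_corpus(model, corpus: Sequence[AnnotatedDocument]) -> EvalReport:
    """Run ``model`` on every document and micro-average the counts.

    ``model`` must expose ``predict_tagged(document) -> TaggedSequence``
    over the same tokenization used for the gold tags.
    """
    if not corpus:
        raise ValueError("cannot evaluate on an empty corpus")
    pairs = []
    for doc in corpus:
        gold = spans_to_bio(doc)
        pred = model.predict_tagged(doc.document)
        pairs.append((gold, pred))
    return evaluate_pairs(pairs)
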