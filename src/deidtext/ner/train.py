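"""Minibatch CRF training with Adam, early stopping and optional EMA.

The training unit is the line-scoped tagged sequence.  After every epoch the
global de-identification F1 (binary identifying-vs-not, token level) is
computed on the validation corpus with the parameters that prediction would
use (the EMA shadow when enabled), and the best-scoring epoch's parameters
are returned.  With a fixed seed and single-threaded NumPy the whole loop is
reproducible bit for bit.
"""

from __future__ import annotations

import copy
import logging
from typing import Sequence

import numpy as np

from ..corpus_io import AnnotatedDocument, TaggedSequence, spans_to_bio, \
    split_by_lines
from ..errors import ModelError
from ..evaluation import ConfusionCounts, prf, token_confusion
from . import _autograd as ag
from .model import (
    ModelConfig,
    TrainedModel,
    apply_ema,
    crf_loss,
    forward_emissions,
    init_parameters,
)
from .vocab import Vocabulary

logger = logging.getLogger(__name__)

__all__ = ["train", "corpus_lines"]


def corpus_lines(corpus: Sequence[AnnotatedDocument]) -> list[TaggedSequence]:
    """All non-empty line-scoped gold sequences of a corpus."""
    lines: list[TaggedSequence] = []
    for doc in corpus:
        seq = spans_to_bio(doc)
        lines.extend(
            ln for ln in split_by_lines(seq, doc.text) if ln.tokens
        )
    return lines


class _Adam:
    def __init__(self, params: dict[str, ag.Tensor], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, clip_norm: float = 5.0):
        self.t += 1
        norm = np.sqrt(sum(
            float((p.grad ** 2).sum())
            for p in self.params.values() if p.grad is not None
        ))
        scale = clip_norm / norm if norm > clip_norm else 1.0
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _validation_f1(model: TrainedModel,
                   val_lines: list[TaggedSequence]) -> float:
    counts = ConfusionCounts()
    for line in val_lines:
        pred_tags = model._decode_line(line)
        counts.merge(
            token_confusion(line, TaggedSequence(line.tokens,
                                                 tuple(pred_tags)))
        )
    return prf(*counts.binary).f1


def train(
    train_corpus: Sequence[AnnotatedDocument],
    val_corpus: Sequence[AnnotatedDocument],
    config: ModelConfig,
) -> TrainedModel:
    """Train one tagger and return the best-validation checkpoint.

    Raises :class:`ModelError` on empty corpora or numerical divergence.
    """
    if not train_corpus or not val_corpus:
        raise ModelError("training and validation corpora must be non-empty")
    train_lines = corpus_lines(train_corpus)
    val_lines = corpus_lines(val_corpus)
    if not train_lines:
        raise ModelError("no non-empty training lines")
    vocab = Vocabulary.build(train_lines)

    rng = np.random.default_rng(config.seed)
    raw = init_parameters(config, vocab, rng)
    params = {k: ag.parameter(v) for k, v in raw.items()}
    opt = _Adam(params, config.learning_rate)
    ema = (
        {k: p.data.copy() for k, p in params.items()}
        if config.use_ema else None
    )

    def snapshot() -> TrainedModel:
        return TrainedModel(
            config=config, vocab=vocab,
            params={k: p.data.copy() for k, p in params.items()},
            ema=copy.deepcopy(ema),
        )

    best: TrainedModel | None = None
    best_f1 = -np.inf
    epochs_since_best = 0
    history: list[dict] = []

    n = len(train_lines)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_nll = 0.0
        for lo in range(0, n, config.batch_size):
            batch = order[lo: lo + config.batch_size]
            opt.zero_grad()
            losses = []
            for idx in batch:
                seq = train_lines[idx]
                emissions = forward_emissions(
                    params, config, vocab, seq, training=True, rng=rng
                )
                tag_ids = np.array([vocab.tags[t] for t in seq.tags])
                losses.append(crf_loss(emissions, params["transitions"],
                                       tag_ids))
            loss = losses[0]
            for other in losses[1:]:
                loss = loss + other
            loss = (1.0 / len(batch)) * loss
            if not np.isfinite(loss.data):
                raise ModelError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            total_nll += float(loss.data) * len(batch)
            loss.backward()
            opt.step()
            if ema is not None:
                ema = apply_ema(
                    ema, {k: p.data for k, p in params.items()},
                    config.ema_decay,
                )
        mean_nll = total_nll / n
        current = snapshot()
        val_f1 = _validation_f1(current, val_lines)
        history.append(
            {"epoch": epoch, "train_nll": mean_nll, "val_f1": val_f1}
        )
        logger.info("epoch %d: train NLL %.4f, val deid F1 %.4f",
                    epoch, mean_nll, val_f1)
        if val_f1 > best_f1:
            best, best_f1, epochs_since_best = current, val_f1, 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    assert best is not None
    best.history = history
    return best
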