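"""The three BiLSTM-CRF sequence-tagging architectures.

All three share a word-level bidirectional LSTM whose per-token outputs are
projected linearly to tag scores (the emission matrix) consumed by a
linear-chain CRF.  They differ in the character channel concatenated to the
word embedding:

``lstm-crf``
    no character channel (word embeddings only);
``lstm-lstm-crf``
    a character BiLSTM per token, final forward and backward states
    concatenated;
``conv-lstm-crf``
    a width-3 character convolution with ReLU and max-over-time pooling.

Prediction optionally uses an exponential moving average (EMA) of the
weights: a shadow copy updated after every optimizer step and swapped in at
inference, which smooths out minibatch noise late in training.

Implemented in NumPy on a small reverse-mode autograd core; float64 and
single-threaded, so a fixed seed reproduces training bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..corpus_io import (
    Document,
    EntitySpan,
    TaggedSequence,
    bio_to_spans,
    repair_bio,
    split_by_lines,
    tokenize,
)
from ..errors import ModelError
from . import _autograd as ag
from .crf import crf_nll, start_stop_indices, viterbi_decode
from .vocab import Vocabulary

ARCHITECTURES = ("lstm-crf", "lstm-lstm-crf", "conv-lstm-crf")


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow common BiLSTM-CRF practice
    (100-d word vectors, 25-d characters, dropout 0.5, Adam at 1e-3)."""

    architecture: str = "lstm-lstm-crf"
    word_dim: int = 100
    char_dim: int = 25
    char_hidden: int = 25
    word_hidden: int = 100
    dropout: float = 0.5
    use_ema: bool = False
    ema_decay: float = 0.999
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0
    #: optional GloVe/word2vec-style text file ("word v1 ... vd" per line);
    #: known words get their pretrained row, the rest stay random
    embeddings_path: str | None = None

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ModelError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {ARCHITECTURES}"
            )
        if not (0 <= self.dropout < 1):
            raise ModelError("dropout must be in [0, 1)")
        if not (0 < self.ema_decay < 1):
            raise ModelError("ema_decay must be in (0, 1)")

    @property
    def has_char_channel(self) -> bool:
        return self.architecture != "lstm-crf"

    @property
    def char_out_dim(self) -> int:
        return 2 * self.char_hidden if self.has_char_channel else 0


def _uniform(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def _lstm_params(rng, input_dim: int, hidden: int) -> dict[str, np.ndarray]:
    w = _glorot(rng, input_dim + hidden, 4 * hidden)
    b = np.zeros(4 * hidden)
    b[hidden:2 * hidden] = 1.0  # forget-gate bias
    return {"w": w, "b": b}


def init_parameters(
    config: ModelConfig, vocab: Vocabulary, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """All learned arrays, keyed by name.  Word/char embeddings are random
    uniform ±0.05 by default; pretrained vectors may overwrite rows later."""
    K = vocab.n_tags
    p: dict[str, np.ndarray] = {}
    p["word_emb"] = _uniform(rng, (vocab.n_words, config.word_dim), 0.05)
    input_dim = config.word_dim + config.char_out_dim
    if config.has_char_channel:
        p["char_emb"] = _uniform(rng, (vocab.n_chars, config.char_dim), 0.05)
        if config.architecture == "lstm-lstm-crf":
            for d in ("fw", "bw"):
                lp = _lstm_params(rng, config.char_dim, config.char_hidden)
                p[f"char_lstm_{d}_w"] = lp["w"]
                p[f"char_lstm_{d}_b"] = lp["b"]
        else:  # conv-lstm-crf: width-3 filters, one per char-output unit
            p["char_conv_w"] = _glorot(
                rng, 3 * config.char_dim, config.char_out_dim
            )
            p["char_conv_b"] = np.zeros(config.char_out_dim)
    for d in ("fw", "bw"):
        lp = _lstm_params(rng, input_dim, config.word_hidden)
        p[f"word_lstm_{d}_w"] = lp["w"]
        p[f"word_lstm_{d}_b"] = lp["b"]
    p["proj_w"] = _glorot(rng, 2 * config.word_hidden, K)
    p["proj_b"] = np.zeros(K)
    p["transitions"] = _uniform(rng, (K + 2, K + 2), 0.05)
    if config.embeddings_path:
        load_pretrained_embeddings(config.embeddings_path, vocab,
                                   p["word_emb"])
    return p


def load_pretrained_embeddings(
    path: str | Path, vocab: Vocabulary, word_emb: np.ndarray
) -> int:
    """Overwrite embedding rows from a GloVe-style text file in place.

    Each line is ``word v1 ... vd``; words are matched after lowercasing
    and unknown words are skipped.  Returns the number of rows loaded.
    A dimension mismatch raises :class:`ModelError`.
    """
    dim = word_emb.shape[1]
    loaded = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word = parts[0].lower()
            if len(parts) - 1 != dim:
                raise ModelError(
                    f"{path}:{lineno}: vector has {len(parts) - 1} "
                    f"dimensions, model expects {dim}"
                )
            idx = vocab.words.get(word)
            if idx is not None:
                word_emb[idx] = np.asarray(parts[1:], dtype=np.float64)
                loaded += 1
    return loaded


def parameter_count(config: ModelConfig, vocab: Vocabulary) -> int:
    """Closed-form total number of learned scalars implied by the config."""
    K = vocab.n_tags
    H = config.word_hidden
    n = vocab.n_words * config.word_dim
    input_dim = config.word_dim + config.char_out_dim
    if config.has_char_channel:
        n += vocab.n_chars * config.char_dim
        ch = config.char_hidden
        if config.architecture == "lstm-lstm-crf":
            n += 2 * ((config.char_dim + ch) * 4 * ch + 4 * ch)
        else:
            n += 3 * config.char_dim * config.char_out_dim + config.char_out_dim
    n += 2 * ((input_dim + H) * 4 * H + 4 * H)
    n += 2 * H * K + K
    n += (K + 2) ** 2
    return n


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _lstm_scan(
    xs: ag.Tensor, mask: np.ndarray | None, w: ag.Tensor, b: ag.Tensor,
    hidden: int,
) -> list[ag.Tensor]:
    """Run an LSTM over ``xs`` of shape (T, B, D); returns per-step hidden
    states (B, hidden).  ``mask`` (T, B, 1) freezes state on padded steps."""
    T, B = xs.shape[0], xs.shape[1]
    h = ag.Tensor(np.zeros((B, hidden)))
    c = ag.Tensor(np.zeros((B, hidden)))
    outs: list[ag.Tensor] = []
    for t in range(T):
        x = xs[t]
        z = ag.concat([x, h], axis=1) @ w + b
        i = ag.sigmoid(z[:, :hidden])
        f = ag.sigmoid(z[:, hidden:2 * hidden])
        g = ag.tanh(z[:, 2 * hidden:3 * hidden])
        o = ag.sigmoid(z[:, 3 * hidden:])
        c_new = f * c + i * g
        h_new = o * ag.tanh(c_new)
        if mask is not None:
            m = ag.Tensor(mask[t])
            c = m * c_new + (1.0 - mask[t]) * c
            h = m * h_new + (1.0 - mask[t]) * h
        else:
            c, h = c_new, h_new
        outs.append(h)
    return outs


def _char_matrix(vocab: Vocabulary, words: list[str]):
    """Pad per-word char ids into (B, L) plus mask and reversed copy."""
    ids = [vocab.char_ids(w) for w in words]
    L = max(3, max(len(i) for i in ids))
    B = len(ids)
    mat = np.zeros((B, L), dtype=np.intp)
    rev = np.zeros((B, L), dtype=np.intp)
    mask = np.zeros((B, L, 1))
    for i, row in enumerate(ids):
        mat[i, : len(row)] = row
        rev[i, : len(row)] = row[::-1]
        mask[i, : len(row), 0] = 1.0
    return mat, rev, mask


def _char_vectors(
    params: dict[str, ag.Tensor], config: ModelConfig, vocab: Vocabulary,
    words: list[str],
) -> ag.Tensor:
    """(B, 2*char_hidden) character representation per word."""
    mat, rev, mask = _char_matrix(vocab, words)
    emb = ag.take_rows(params["char_emb"], mat)        # (B, L, char_dim)
    if config.architecture == "lstm-lstm-crf":
        emb_rev = ag.take_rows(params["char_emb"], rev)
        # (L, B, D) time-major scans with state frozen past each word's end,
        # so the last step holds the true final state
        xs_f = ag.Tensor(np.transpose(emb.data, (1, 0, 2)), (emb,))
        xs_f._backward = lambda g: ag._accum(emb, np.transpose(g, (1, 0, 2)))
        xs_b = ag.Tensor(np.transpose(emb_rev.data, (1, 0, 2)), (emb_rev,))
        xs_b._backward = lambda g: ag._accum(
            emb_rev, np.transpose(g, (1, 0, 2)))
        m = np.transpose(mask, (1, 0, 2))
        h_f = _lstm_scan(xs_f, m, params["char_lstm_fw_w"],
                         params["char_lstm_fw_b"], config.char_hidden)[-1]
        h_b = _lstm_scan(xs_b, m, params["char_lstm_bw_w"],
                         params["char_lstm_bw_b"], config.char_hidden)[-1]
        return ag.concat([h_f, h_b], axis=1)
    # conv-lstm-crf: width-3 windows over characters, ReLU, max over time
    B, L = mat.shape
    pad = ag.Tensor(np.zeros((B, 1, config.char_dim)))
    padded = ag.concat([pad, emb, pad], axis=1)        # (B, L+2, D)
    windows = ag.concat(
        [padded[:, 0:L, :], padded[:, 1:L + 1, :], padded[:, 2:L + 2, :]],
        axis=2,
    )                                                   # (B, L, 3D)
    flat = windows.reshape(B * L, 3 * config.char_dim)
    z = ag.relu(flat @ params["char_conv_w"] + params["char_conv_b"])
    z = z.reshape(B, L, config.char_out_dim)
    neg = (mask - 1.0) * 1e9                            # -1e9 on padding
    z = z * ag.Tensor(mask) + ag.Tensor(neg)
    return ag.amax(z, axis=1)


def forward_emissions(
    params: dict[str, ag.Tensor], config: ModelConfig, vocab: Vocabulary,
    seq: TaggedSequence, *, training: bool = False,
    rng: np.random.Generator | None = None,
) -> ag.Tensor:
    """Emission matrix (T, n_tags) for one line-scoped token sequence."""
    if not seq.tokens:
        raise ModelError("cannot encode an empty token sequence")
    words = [t.text for t in seq.tokens]
    word_ids = np.array([vocab.word_id(w) for w in words], dtype=np.intp)
    x = ag.take_rows(params["word_emb"], word_ids)      # (T, word_dim)
    if config.has_char_channel:
        x = ag.concat([x, _char_vectors(params, config, vocab, words)], axis=1)
    if training and config.dropout > 0:
        x = ag.dropout(x, config.dropout, rng)
    T = len(words)
    xs = x.reshape(T, 1, x.shape[1])
    outs_f = _lstm_scan(xs, None, params["word_lstm_fw_w"],
                        params["word_lstm_fw_b"], config.word_hidden)
    # backward direction: reverse time, scan, reverse back
    xs_b = ag.Tensor(x.data[::-1].copy(), (x,))
    xs_b._backward = lambda g: ag._accum(x, g[::-1].copy())
    xs_b = xs_b.reshape(T, 1, x.shape[1])
    outs_b = _lstm_scan(xs_b, None, params["word_lstm_bw_w"],
                        params["word_lstm_bw_b"], config.word_hidden)
    outs_b = outs_b[::-1]
    hs = [ag.concat([f, b], axis=1) for f, b in zip(outs_f, outs_b)]
    h = ag.concat(hs, axis=0) if T > 1 else hs[0]
    if training and config.dropout > 0:
        h = ag.dropout(h, config.dropout, rng)
    return h @ params["proj_w"] + params["proj_b"]


def crf_loss(
    emissions: ag.Tensor, transitions: ag.Tensor, tag_ids: np.ndarray
) -> ag.Tensor:
    """Autograd CRF negative log-likelihood (same recursion as
    :func:`deidtext.ner.crf.crf_nll`, differentiable)."""
    T, K = emissions.shape
    start, stop = start_stop_indices(K)
    alpha = transitions[start, :K] + emissions[0]
    for t in range(1, T):
        alpha = ag.logsumexp(
            alpha.reshape(K, 1) + transitions[:K, :K], axis=0
        ) + emissions[t]
    log_z = ag.logsumexp(alpha + transitions[:K, stop], axis=0)
    rows = np.arange(T)
    gold = emissions[rows, tag_ids].sum()
    gold = gold + transitions[start, tag_ids[0]]
    if T > 1:
        gold = gold + transitions[tag_ids[:-1], tag_ids[1:]].sum()
    gold = gold + transitions[tag_ids[-1], stop]
    return log_z - gold


# ---------------------------------------------------------------------------
# EMA
# ---------------------------------------------------------------------------

def apply_ema(
    shadow: dict[str, np.ndarray],
    current: dict[str, np.ndarray],
    decay: float,
) -> dict[str, np.ndarray]:
    """One EMA update: ``shadow' = decay * shadow + (1 - decay) * current``."""
    if set(shadow) != set(current):
        raise ModelError("EMA shadow and current parameter names differ")
    out = {}
    for k, s in shadow.items():
        c = np.asarray(current[k])
        if s.shape != c.shape:
            raise ModelError(f"EMA shape mismatch for {k}: {s.shape} vs {c.shape}")
        out[k] = decay * s + (1.0 - decay) * c
    return out


# ---------------------------------------------------------------------------
# Trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained tagger: config, vocabulary, parameters, optional EMA shadow
    and the per-epoch training log."""

    config: ModelConfig
    vocab: Vocabulary
    params: dict[str, np.ndarray]
    ema: dict[str, np.ndarray] | None = None
    history: list[dict] = field(default_factory=list)

    def inference_params(self) -> dict[str, np.ndarray]:
        """EMA shadow when enabled, raw parameters otherwise."""
        if self.config.use_ema and self.ema is not None:
            return self.ema
        return self.params

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- encoding / decoding -------------------------------------------------

    def _tensor_params(self) -> dict[str, ag.Tensor]:
        return {k: ag.Tensor(v) for k, v in self.inference_params().items()}

    def encode_tokens(self, seq: TaggedSequence) -> np.ndarray:
        """Emission matrix (T, n_tags) for one token sequence."""
        return forward_emissions(
            self._tensor_params(), self.config, self.vocab, seq
        ).data

    def _decode_line(self, seq: TaggedSequence) -> list[str]:
        emissions = self.encode_tokens(seq)
        transitions = self.inference_params()["transitions"]
        path, _score = viterbi_decode(emissions, transitions)
        names = self.vocab.tag_names
        return [names[i] for i in path]

    def predict_tagged(self, doc: Document) -> TaggedSequence:
        """Tokenize, tag line by line, and repair invalid BIO output."""
        tokens = tuple(tokenize(doc.text))
        if not tokens:
            return TaggedSequence((), ())
        base = TaggedSequence(tokens, ("O",) * len(tokens))
        tags: list[str] = []
        for line in split_by_lines(base, doc.text):
            tags.extend(self._decode_line(line))
        return TaggedSequence(tokens, tuple(repair_bio(tags)))

    def predict(self, doc: Document) -> list[EntitySpan]:
        """End-to-end tagging of a raw document into entity spans."""
        seq = self.predict_tagged(doc)
        if not seq.tokens:
            return []
        return bio_to_spans(seq, doc.text)

    def line_nll(self, seq: TaggedSequence) -> float:
        """CRF negative log-likelihood of a gold-tagged line under the
        inference parameters."""
        emissions = self.encode_tokens(seq)
        tag_ids = np.array([self.vocab.tags[t] for t in seq.tags])
        return crf_nll(emissions, self.inference_params()["transitions"],
                       tag_ids)

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(asdict(self.config), indent=1), encoding="utf-8"
        )
        (directory / "vocab.json").write_text(
            json.dumps(
                {"words": self.vocab.words, "chars": self.vocab.chars,
                 "tags": self.vocab.tags},
            ), encoding="utf-8"
        )
        np.savez(directory / "params.npz", **self.params)
        if self.ema is not None:
            np.savez(directory / "ema.npz", **self.ema)
        (directory / "history.json").write_text(
            json.dumps(self.history, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        try:
            config = ModelConfig(**json.loads(
                (directory / "config.json").read_text(encoding="utf-8")))
            vdata = json.loads(
                (directory / "vocab.json").read_text(encoding="utf-8"))
            vocab = Vocabulary(words=vdata["words"], chars=vdata["chars"],
                               tags=vdata["tags"])
            with np.load(directory / "params.npz") as z:
                params = {k: z[k] for k in z.files}
            ema = None
            if (directory / "ema.npz").exists():
                with np.load(directory / "ema.npz") as z:
                    ema = {k: z[k] for k in z.files}
            history = []
            if (directory / "history.json").exists():
                history = json.loads(
                    (directory / "history.json").read_text(encoding="utf-8"))
        except (OSError, KeyError, ValueError) as exc:
            raise ModelError(f"cannot load checkpoint {directory}: {exc}")
        model = cls(config=config, vocab=vocab, params=params, ema=ema,
                    history=history)
        expected = parameter_count(config, vocab)
        if model.parameter_count() != expected:
            raise ModelError(
                f"checkpoint integrity error: {model.parameter_count()} "
                f"parameters stored, {expected} implied by config/vocabulary"
            )
        return model
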