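import numpy as np
import pytest

import deidtext as dt
from deidtext.ner import _autograd as ag
from deidtext.ner.model import ModelConfig, forward_emissions, crf_loss, \
    init_parameters
from deidtext.ner.train import _Adam
from deidtext.ner.vocab import Vocabulary


@pytest.fixture(scope="session")
def gazetteers():
    return dt.builtin_gazetteers()


@pytest.fixture(scope="session")
def small_corpus(gazetteers):
    """A 60-document mixed-profile synthetic corpus (fixed seed)."""
    return dt.generate_corpus(
        60, {"headered": 0.8, "dept7": 0.2}, dt.TRAIN_TARGET, gazetteers,
        np.random.default_rng(123),
    )


def make_overfit_sequence():
    """One ~10-token annotated line exercising five entity categories."""
    text = ("PACIENTE: María García Pérez 12345678 14/03/2018 "
            "Hospital La Fe sin hallazgos")
    doc = dt.Document("overfit-1", text)

    def span(surface, label):
        i = text.index(surface)
        return dt.EntitySpan(i, i + len(surface), label, surface)

    annotated = dt.AnnotatedDocument(doc, (
        span("PACIENTE:", "CAB"),
        span("María García Pérez", "NAME"),
        span("12345678", "NUM"),
        span("14/03/2018", "FECHA"),
        span("Hospital La Fe", "INST"),
    ))
    return annotated


def overfit_nll(architecture: str, max_steps: int = 200,
                target: float = 0.1) -> tuple[float, int]:
    """Train one architecture on a single sequence; returns the first NLL
    below ``target`` (or the final NLL) and the number of steps used."""
    seq = dt.spans_to_bio(make_overfit_sequence())
    config = ModelConfig(
        architecture=architecture, word_dim=32, char_dim=16, char_hidden=16,
        word_hidden=32, dropout=0.0, epochs=1, seed=0,
    )
    vocab = Vocabulary.build([seq])
    rng = np.random.default_rng(0)
    params = {k: ag.parameter(v)
              for k, v in init_parameters(config, vocab, rng).items()}
    opt = _Adam(params, 1e-2)
    tag_ids = np.array([vocab.tags[t] for t in seq.tags])
    nll = np.inf
    for step in range(max_steps):
        opt.zero_grad()
        emissions = forward_emissions(params, config, vocab, seq)
        loss = crf_loss(emissions, params["transitions"], tag_ids)
        loss.backward()
        opt.step()
        nll = float(loss.data)
        if nll < target:
            break
    return nll, step + 1
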