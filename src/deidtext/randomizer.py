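"""Category-preserving surrogate substitution (entity randomization).

Detected entities are replaced with synthetic values of the same category:
names with gazetteer names (frequency-weighted), places with municipalities
(population-weighted), institutions and addresses with index entries, dates
with freshly generated dates in the same format family, and identifier codes
with strings matching the original's character-class mask.  Section headers
(CAB) are kept verbatim — they carry the report structure, not identity.

Two guarantees drive the design:

* a surrogate is **never** equal to the original surface (so nothing leaks
  through an "unchanged" value), and
* all text outside entity spans is byte-identical to the input, so residual
  tagger misses are indistinguishable from substituted text.

The audit trail stores only categories and lengths — never the original
surfaces, which would defeat the purpose of de-identification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import AnnotatedDocument, Document, EntitySpan
from .errors import DeidTextError, ExhaustionError
from .gazetteers import GazetteerSet, weighted_sample
from .synthetic_corpus import random_date, random_pseudo_word

__all__ = ["DeidDocument", "make_surrogate", "deidentify",
           "deidentify_with_model"]


@dataclass
class DeidDocument:
    """A de-identified report: new text, surrogate spans, anonymous audit."""

    text: str
    spans: tuple[EntitySpan, ...]
    #: (category, original_length, surrogate_length) per substitution;
    #: deliberately free of original surfaces.
    audit: list[tuple[str, int, int]] = field(default_factory=list)


_WRITTEN_DATE_RE = re.compile(
    r"^\s*\d{1,2}\s+de\s+\S+\s+de\s+\d{4}\s*$", re.IGNORECASE
)

_synth_word = random_pseudo_word  # gazetteer-exhaustion fallback surface


def _date_surrogate(original: str, rng: np.random.Generator) -> str:
    """A fresh valid date rendered in the same format family as ``original``."""
    if _WRITTEN_DATE_RE.match(original):
        family = "written"
    elif "-" in original:
        family = "dash"
    else:
        family = "slash"
    for _ in range(1000):
        raw = random_date(rng)
        if _WRITTEN_DATE_RE.match(raw):
            got = "written"
        elif "-" in raw:
            got = "dash"
        else:
            got = "slash"
        if got == family and raw != original:
            return raw
    raise DeidTextError("could not generate a distinct date surrogate")


def _mask_surrogate(original: str, rng: np.random.Generator) -> str:
    """A string matching ``original``'s character-class mask: digits map to
    random digits, letters to random letters of the same case, everything
    else is preserved."""
    upper = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for _ in range(1000):
        chars = []
        for c in original:
            if c.isdigit():
                chars.append(str(rng.integers(0, 10)))
            elif c.isalpha() and c.isupper():
                chars.append(upper[rng.integers(0, 26)])
            elif c.isalpha():
                chars.append(upper[rng.integers(0, 26)].lower())
            else:
                chars.append(c)
        out = "".join(chars)
        if out != original:
            return out
    # a mask with no free position (all separators) cannot differ; refuse
    raise DeidTextError(
        f"mask of length {len(original)} admits no distinct surrogate"
    )


def _single_token_sample(gaz, rng, exclude: set[str], tries: int = 50) -> str:
    """Sample a surface that is a single whitespace-delimited word."""
    for _ in range(tries):
        s = weighted_sample(gaz, rng, exclude)
        if " " not in s:
            return s
    raise ExhaustionError(f"no single-word entry drawn from {gaz.category}")


def _name_surrogate(
    original: str, gazetteers: GazetteerSet, rng: np.random.Generator
) -> str:
    """A given-name + surname(s) combination with the original's word count."""
    n_words = max(1, len(original.split()))
    given = gazetteers.given or gazetteers["NAME"]
    surname = gazetteers.surname or gazetteers["NAME"]
    for _ in range(50):
        try:
            parts = [_single_token_sample(given, rng, {original})]
            while len(parts) < n_words:
                parts.append(_single_token_sample(surname, rng, {original}))
        except ExhaustionError:
            break
        out = " ".join(parts)
        if out != original:
            return out
    out = " ".join(_synth_word(rng) for _ in range(n_words))
    while out == original:  # pragma: no cover - astronomically unlikely
        out = " ".join(_synth_word(rng) for _ in range(n_words))
    return out


def make_surrogate(
    span: EntitySpan, gazetteers: GazetteerSet, rng: np.random.Generator
) -> str:
    """A synthetic replacement of the same category, never equal to the
    original surface (except CAB, which is returned unchanged by design)."""
    label, original = span.label, span.surface
    if label == "CAB":
        return original
    if label == "FECHA":
        return _date_surrogate(original, rng)
    if label == "NUM":
        return _mask_surrogate(original, rng)
    if label == "NAME":
        return _name_surrogate(original, gazetteers, rng)
    if label in ("LOC", "INST", "DIR"):
        gaz = gazetteers.get(label)
        if gaz is not None and len(gaz):
            try:
                return weighted_sample(gaz, rng, {original})
            except ExhaustionError:
                pass
        out = _synth_word(rng)
        if label == "DIR":
            out = f"Calle {out} {int(rng.integers(1, 200))}"
        while out == original:  # pragma: no cover
            out = _synth_word(rng)
        return out
    raise DeidTextError(f"no substitution rule for label {label!r}")


def deidentify(
    doc: AnnotatedDocument, gazetteers: GazetteerSet, rng: np.random.Generator
) -> DeidDocument:
    """Replace every non-CAB span of ``doc`` with a category surrogate.

    Spans are processed right to left so earlier offsets stay valid; text
    between spans is byte-identical to the original, and the line count is
    preserved (surrogates never contain newlines).
    """
    text = doc.text
    new_spans: list[EntitySpan] = []
    audit: list[tuple[str, int, int]] = []
    # right-to-left over spans sorted by start
    deltas: list[tuple[EntitySpan, str]] = []
    for span in reversed(doc.spans):
        surrogate = make_surrogate(span, gazetteers, rng)
        if "\n" in surrogate:
            raise DeidTextError("surrogate contains a newline")
        text = text[: span.start] + surrogate + text[span.end:]
        deltas.append((span, surrogate))
        audit.append((span.label, len(span.surface), len(surrogate)))
    # recompute surrogate offsets left to right
    shift = 0
    for span, surrogate in reversed(deltas):
        start = span.start + shift
        end = start + len(surrogate)
        new_spans.append(EntitySpan(start, end, span.label, surrogate))
        shift += len(surrogate) - (span.end - span.start)
    audit.reverse()
    return DeidDocument(text=text, spans=tuple(new_spans), audit=audit)


def deidentify_with_model(
    doc: Document, model, gazetteers: GazetteerSet, rng: np.random.Generator
) -> DeidDocument:
    """Tag ``doc`` with a trained model, then substitute what it found."""
    spans = model.predict(doc)
    annotated = AnnotatedDocument(doc, tuple(spans))
    return deidentify(annotated, gazetteers, rng)
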