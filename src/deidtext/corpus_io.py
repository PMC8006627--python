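"""Documents, entity spans, tokenization, BIO tagging and corpus file formats.

The unit of work throughout the package is the :class:`AnnotatedDocument`: a
report text together with non-overlapping labeled character spans.  This
module converts between that representation, the token/BIO view consumed by
the sequence taggers, and two on-disk formats (CoNLL-2002-style token/tag
files and BRAT standoff), and implements the department-aware train /
validation / test split used for structure-sensitivity experiments.

Conventions
-----------
* Character offsets are 0-based, half-open, counted over Unicode code points
  (the same convention BRAT uses).
* The tag scheme is BIO over the seven entity labels.
* A "sentence" for modeling purposes is one line of the report: clinical
  reports carry signal in their line structure (identifiers often sit alone
  on a line), so lines are never merged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    BoundaryMismatchError,
    IntegrityError,
    OverlapError,
    ParseError,
    SizingError,
)

#: The seven entity labels: section headers, person names, full addresses,
#: populated places, identifying numbers/codes, dates, healthcare institutions.
ENTITY_LABELS = ("CAB", "NAME", "DIR", "LOC", "NUM", "FECHA", "INST")

#: Labels whose tokens count as identifying for the global de-identification
#: metric.  CAB headers are deliberately preserved in de-identified output,
#: so they are not "identifying".
IDENTIFYING_LABELS = ("NAME", "DIR", "LOC", "NUM", "FECHA", "INST")

#: Reserved CoNLL token encoding a report line break (see read/write_conll).
NEWLINE_TOKEN = "-NL-"

_DOCSTART = "-DOCSTART-"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Document:
    """A raw report: identifier, text and a health-department marker.

    The department is a structural-profile tag (an int, or ``"unknown"``):
    some departments produce headerless reports whose identifying entities
    sit alone on lines, and the splitter uses the marker to hold one
    department out as a structurally distinct test set.
    """

    id: str
    text: str
    department: int | str = "unknown"

    def __post_init__(self):
        if not self.id:
            raise ValueError("Document id must be non-empty")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """One labeled region of text: ``[start, end)`` with its surface string."""

    start: int
    end: int
    label: str
    surface: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span offsets [{self.start}, {self.end})")
        if self.label not in ENTITY_LABELS:
            raise ValueError(f"unknown entity label {self.label!r}")


@dataclass(frozen=True)
class AnnotatedDocument:
    """A document plus its entity spans, ordered by start offset."""

    document: Document
    spans: tuple[EntitySpan, ...] = ()

    def __post_init__(self):
        spans = tuple(sorted(self.spans, key=lambda s: (s.start, s.end)))
        object.__setattr__(self, "spans", spans)
        text = self.document.text
        prev_end = -1
        for s in spans:
            if s.end > len(text):
                raise ValueError(f"span {s} exceeds text length {len(text)}")
            if text[s.start:s.end] != s.surface:
                raise IntegrityError(
                    f"span surface {s.surface!r} != text slice "
                    f"{text[s.start:s.end]!r} at [{s.start}, {s.end})"
                )
            if s.start < prev_end:
                raise OverlapError(f"span {s} overlaps its predecessor")
            prev_end = s.end

    @property
    def id(self) -> str:
        return self.document.id

    @property
    def text(self) -> str:
        return self.document.text


@dataclass(frozen=True)
class Token:
    """A token with its character offsets into the source text."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class TaggedSequence:
    """A tokenized document with one BIO tag per token."""

    tokens: tuple[Token, ...]
    tags: tuple[str, ...]

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )


@dataclass
class CorpusSplit:
    """Train / validation / test partition of a corpus."""

    train: list[AnnotatedDocument] = field(default_factory=list)
    validation: list[AnnotatedDocument] = field(default_factory=list)
    test: list[AnnotatedDocument] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Punctuation peeled off the edges of whitespace-delimited chunks.  Internal
# separators are kept so date-like ("14/03/2018") and code-like ("1234-AB")
# surfaces stay single tokens: category surrogates are whole-string
# replacements, so splitting them would fragment NUM/FECHA entities.
_EDGE_PUNCT = set(".,:;()[]{}<>!?¿¡\"'«»“”‘’…·-/\\|")

_CHUNK_RE = re.compile(r"\S+")


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into tokens carrying offsets into the original string.

    Rule: split on whitespace, then peel leading/trailing punctuation
    characters off each chunk as single-character tokens.  Characters
    interior to a chunk are never split, which keeps dates and
    alphanumeric codes whole.  Newlines never occur inside a token.
    """
    tokens: list[Token] = []
    for m in _CHUNK_RE.finditer(text):
        chunk, start = m.group(), m.start()
        lo, hi = 0, len(chunk)
        # peel leading punctuation
        while lo < hi - 1 and chunk[lo] in _EDGE_PUNCT:
            tokens.append(Token(chunk[lo], start + lo, start + lo + 1))
            lo += 1
        # find trailing punctuation run (emitted after the core)
        tail = hi
        while tail > lo + 1 and chunk[tail - 1] in _EDGE_PUNCT:
            tail -= 1
        tokens.append(Token(chunk[lo:tail], start + lo, start + tail))
        for i in range(tail, hi):
            tokens.append(Token(chunk[i], start + i, start + i + 1))
    return tokens


# ---------------------------------------------------------------------------
# Span <-> BIO conversion
# ---------------------------------------------------------------------------

def spans_to_bio(doc: AnnotatedDocument) -> TaggedSequence:
    """Convert character spans to per-token BIO tags.

    Every span boundary must coincide with token boundaries; a span that
    starts or ends inside a token raises :class:`BoundaryMismatchError`.
    """
    tokens = tokenize(doc.text)
    tags = ["O"] * len(tokens)
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i for i, t in enumerate(tokens)}
    for span in doc.spans:
        if span.start not in starts or span.end not in ends:
            raise BoundaryMismatchError(
                f"span {span.label} [{span.start}, {span.end}) "
                f"{span.surface!r} does not align with token boundaries"
            )
        first, last = starts[span.start], ends[span.end]
        tags[first] = f"B-{span.label}"
        for i in range(first + 1, last + 1):
            tags[i] = f"I-{span.label}"
    return TaggedSequence(tuple(tokens), tuple(tags))


def repair_bio(tags: Sequence[str]) -> list[str]:
    """Make a raw tag sequence valid: a dangling ``I-X`` becomes ``B-X``."""
    out: list[str] = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            label = tag[2:]
            if prev not in (f"B-{label}", f"I-{label}"):
                tag = f"B-{label}"
        out.append(tag)
        prev = tag
    return out


def bio_to_spans(seq: TaggedSequence, text: str) -> list[EntitySpan]:
    """Convert BIO tags back to character spans (inverse of spans_to_bio).

    Invalid sequences are repaired first, so this is total on raw model
    output.
    """
    tags = repair_bio(seq.tags)
    spans: list[EntitySpan] = []
    i = 0
    while i < len(tags):
        tag = tags[i]
        if tag.startswith("B-"):
            label = tag[2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{label}":
                j += 1
            start = seq.tokens[i].start
            end = seq.tokens[j - 1].end
            spans.append(EntitySpan(start, end, label, text[start:end]))
            i = j
        else:
            i += 1
    return spans


# ---------------------------------------------------------------------------
# CoNLL-2002-style corpus files
# ---------------------------------------------------------------------------

_VALID_TAGS = frozenset(
    ["O"] + [f"{p}-{lab}" for p in ("B", "I") for lab in ENTITY_LABELS]
)

_HEADER_RE = re.compile(r"#\s*id=(\S+)\s+dept=(\S+)")


def _doc_lines_to_conll(doc: AnnotatedDocument) -> list[str]:
    dept = doc.document.department
    lines = [f"{_DOCSTART}\tO\t# id={doc.id} dept={dept}"]
    seq = spans_to_bio(doc)
    line_no = 0
    # token line index = number of newlines before token.start
    breaks = [i for i, c in enumerate(doc.text) if c == "\n"]
    bi = 0
    for tok, tag in zip(seq.tokens, seq.tags):
        while bi < len(breaks) and breaks[bi] < tok.start:
            lines.append(f"{NEWLINE_TOKEN}\tO")
            bi += 1
            line_no += 1
        lines.append(f"{tok.text}\t{tag}")
    for _ in range(bi, len(breaks)):
        lines.append(f"{NEWLINE_TOKEN}\tO")
    return lines


def write_conll(corpus: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write a corpus as one ``token<TAB>tag`` pair per line.

    Documents are separated by a blank line and introduced by a
    ``-DOCSTART-`` header carrying id and department as a trailing comment.
    Report line breaks are encoded as the reserved token ``-NL-`` so line
    structure survives the round trip (an empty report line shows up as two
    consecutive ``-NL-`` tokens).
    """
    blocks = ["\n".join(_doc_lines_to_conll(d)) for d in corpus]
    Path(path).write_text("\n\n".join(blocks) + ("\n" if blocks else ""),
                          encoding="utf-8", newline="\n")


def _assemble_document(
    doc_id: str, dept: int | str, rows: list[tuple[str, str]]
) -> AnnotatedDocument:
    """Rebuild text (single-space joined lines) and spans from token rows."""
    lines: list[list[tuple[str, str]]] = [[]]
    for tok, tag in rows:
        if tok == NEWLINE_TOKEN:
            lines.append([])
        else:
            lines[-1].append((tok, tag))
    text_lines: list[str] = []
    tokens: list[Token] = []
    tags: list[str] = []
    offset = 0
    for ln in lines:
        pieces = []
        col = offset
        for tok, tag in ln:
            tokens.append(Token(tok, col, col + len(tok)))
            tags.append(tag)
            pieces.append(tok)
            col += len(tok) + 1
        joined = " ".join(pieces)
        text_lines.append(joined)
        offset += len(joined) + 1
    text = "\n".join(text_lines)
    seq = TaggedSequence(tuple(tokens), tuple(tags))
    spans = bio_to_spans(seq, text)
    return AnnotatedDocument(Document(doc_id, text, dept), tuple(spans))


def read_conll(path: str | Path) -> list[AnnotatedDocument]:
    """Read a corpus written by :func:`write_conll` (dialect documented there)."""
    docs: list[AnnotatedDocument] = []
    doc_id: str | None = None
    dept: int | str = "unknown"
    rows: list[tuple[str, str]] = []
    auto_id = 0

    def flush():
        nonlocal doc_id, rows, auto_id
        if doc_id is None and not rows:
            return
        did = doc_id if doc_id is not None else f"doc{auto_id}"
        auto_id += 1
        docs.append(_assemble_document(did, dept, rows))
        doc_id, rows = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split("\t")
            if cols[0] == _DOCSTART:
                flush()
                doc_id, dept = f"doc{auto_id}", "unknown"
                if len(cols) >= 3:
                    m = _HEADER_RE.search(cols[2])
                    if m:
                        doc_id = m.group(1)
                        d = m.group(2)
                        dept = int(d) if d.isdigit() else d
                continue
            if len(cols) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(cols)}: "
                    f"{line!r}", line=lineno,
                )
            tok, tag = cols
            if tag not in _VALID_TAGS:
                raise ParseError(f"unknown tag {tag!r}", line=lineno)
            rows.append((tok, tag))
    flush()
    return docs


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------

def read_brat(txt_path: str | Path, ann_path: str | Path) -> AnnotatedDocument:
    """Read a BRAT ``.txt``/``.ann`` pair (only ``T`` annotation lines).

    Every annotation's surface is validated against the text slice; a
    mismatch raises :class:`IntegrityError` naming the annotation id, and
    overlapping spans raise :class:`OverlapError`.
    """
    txt_path, ann_path = Path(txt_path), Path(ann_path)
    text = txt_path.read_text(encoding="utf-8")
    spans: list[EntitySpan] = []
    for lineno, raw in enumerate(
        ann_path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not raw.strip() or not raw.startswith("T"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ParseError(f"malformed annotation line {raw!r}", line=lineno)
        ann_id = parts[0]
        ref = parts[1].split()
        if len(ref) != 3:
            raise ParseError(
                f"annotation {ann_id}: expected 'LABEL START END'", line=lineno
            )
        label, start, end = ref[0], int(ref[1]), int(ref[2])
        surface = parts[2] if len(parts) > 2 else ""
        if text[start:end] != surface:
            raise IntegrityError(
                f"annotation {ann_id}: surface {surface!r} != text slice "
                f"{text[start:end]!r}"
            )
        spans.append(EntitySpan(start, end, label, surface))
    doc_id = txt_path.stem
    return AnnotatedDocument(Document(doc_id, text), tuple(spans))


def write_brat(doc: AnnotatedDocument, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``<id>.txt`` and ``<id>.ann`` into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt_path = out_dir / f"{doc.id}.txt"
    ann_path = out_dir / f"{doc.id}.ann"
    txt_path.write_text(doc.text, encoding="utf-8", newline="\n")
    lines = [
        f"T{i}\t{s.label} {s.start} {s.end}\t{s.surface}"
        for i, s in enumerate(doc.spans, start=1)
    ]
    ann_path.write_text("\n".join(lines) + ("\n" if lines else ""),
                        encoding="utf-8", newline="\n")
    return txt_path, ann_path


# ---------------------------------------------------------------------------
# Department-aware splitting
# ---------------------------------------------------------------------------

def _sizes_from_ratios(ratios: Sequence[float], n: int) -> tuple[int, int, int]:
    """Largest-remainder apportionment of ``n`` documents into three parts."""
    total = float(sum(ratios))
    if total <= 0 or len(ratios) != 3 or any(r < 0 for r in ratios):
        raise SizingError(f"invalid split ratios {ratios!r}")
    quotas = [r / total * n for r in ratios]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    order = np.argsort([s - q for s, q in zip(sizes, quotas)])
    for i in range(rem):
        sizes[order[i]] += 1
    return tuple(sizes)  # type: ignore[return-value]


def split_corpus(
    corpus: Sequence[AnnotatedDocument],
    heldout_department: int | str,
    n_heldout_in_train: int,
    ratios: Sequence[float],
    seed: int,
) -> CorpusSplit:
    """Partition a corpus into train / validation / test, holding one
    department out as the test set.

    The test set is drawn exclusively from ``heldout_department``; the
    validation set excludes that department entirely; the training set mixes
    both, with exactly ``n_heldout_in_train`` held-out-department documents.
    The held-out department must therefore contain exactly
    ``n_test + n_heldout_in_train`` documents, otherwise a
    :class:`SizingError` is raised.  Deterministic given ``seed``.
    """
    docs = sorted(corpus, key=lambda d: d.id)
    ids = [d.id for d in docs]
    if len(set(ids)) != len(ids):
        raise SizingError("duplicate document ids in corpus")
    n_train, n_val, n_test = _sizes_from_ratios(ratios, len(docs))

    held = [d for d in docs if d.document.department == heldout_department]
    rest = [d for d in docs if d.document.department != heldout_department]
    if len(held) < n_test + n_heldout_in_train:
        raise SizingError(
            f"held-out department {heldout_department!r} has {len(held)} "
            f"documents; need {n_test} (test) + {n_heldout_in_train} (train)"
        )
    if len(held) > n_test + n_heldout_in_train:
        raise SizingError(
            f"held-out department {heldout_department!r} has {len(held)} "
            f"documents but only {n_test + n_heldout_in_train} slots "
            "(test + train quota); validation may not contain it"
        )
    if len(rest) != (n_train - n_heldout_in_train) + n_val:
        raise SizingError(
            f"{len(rest)} non-held-out documents cannot fill "
            f"{n_train - n_heldout_in_train} train + {n_val} validation slots"
        )

    rng = np.random.default_rng(seed)
    held_perm = [held[i] for i in rng.permutation(len(held))]
    rest_perm = [rest[i] for i in rng.permutation(len(rest))]

    test = held_perm[:n_test]
    train = held_perm[n_test:] + rest_perm[: n_train - n_heldout_in_train]
    validation = rest_perm[n_train - n_heldout_in_train:]
    return CorpusSplit(train=train, validation=validation, test=test)


def split_by_lines(seq: TaggedSequence, text: str) -> list[TaggedSequence]:
    """Split a document-level tagged sequence into line-scoped sequences.

    The report line is the modeling sentence unit: entities never cross
    lines and headerless reports carry entities alone on lines, so lines
    are the natural context window.  Empty lines yield no sequence.
    """
    if not seq.tokens:
        return []
    breaks = [i for i, c in enumerate(text) if c == "\n"]
    out: list[TaggedSequence] = []
    cur_toks: list[Token] = []
    cur_tags: list[str] = []
    bi = 0
    for tok, tag in zip(seq.tokens, seq.tags):
        crossed = False
        while bi < len(breaks) and breaks[bi] < tok.start:
            bi += 1
            crossed = True
        if crossed and cur_toks:
            out.append(TaggedSequence(tuple(cur_toks), tuple(cur_tags)))
            cur_toks, cur_tags = [], []
        cur_toks.append(tok)
        cur_tags.append(tag)
    if cur_toks:
        out.append(TaggedSequence(tuple(cur_toks), tuple(cur_tags)))
    return out


def with_spans(doc: AnnotatedDocument,
               spans: Iterable[EntitySpan]) -> AnnotatedDocument:
    """Return a copy of ``doc`` with ``spans`` substituted."""
    return replace(doc, spans=tuple(spans))
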