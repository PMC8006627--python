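"""Gazetteer-based automatic pre-annotation and corpus-construction filters.

Pre-annotation is deliberately context-blind: a lowercase anatomical word
that doubles as a surname ("cabeza") *will* be matched.  The corpus filters
downstream — keeping only documents with at least two NAME spans — are what
push such false hits out of the final corpus, mirroring how a first-pass
dictionary annotation is cleaned up before manual revision.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedDocument, Document, EntitySpan
from .gazetteers import GazetteerSet, match_entities

__all__ = [
    "preannotate",
    "filter_min_names",
    "sample_fraction",
    "CATEGORY_PRIORITY",
]

#: Tie-break priority for equal-length overlapping candidates: the more
#: specific gazetteers win.
CATEGORY_PRIORITY = ("INST", "DIR", "LOC", "NAME", "NUM", "FECHA")


def preannotate(doc: Document, gazetteers: GazetteerSet) -> AnnotatedDocument:
    """Dictionary-match every gazetteer against ``doc`` and merge the hits.

    Conflicts are resolved longest-match-first, then by the fixed category
    priority, then left to right; the result never contains overlapping
    spans.
    """
    candidates: list[EntitySpan] = []
    for category, gaz in gazetteers.gazetteers.items():
        candidates.extend(match_entities(doc.text, gaz))
    prio = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    candidates.sort(
        key=lambda s: (-(s.end - s.start), s.start, prio.get(s.label, 99))
    )
    chosen: list[EntitySpan] = []
    for cand in candidates:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    return AnnotatedDocument(doc, tuple(sorted(chosen)))


def filter_min_names(
    corpus: Sequence[AnnotatedDocument], min_count: int = 2
) -> list[AnnotatedDocument]:
    """Keep documents carrying at least ``min_count`` NAME spans.

    Filtering on repeated person-name hits selects documents that genuinely
    contain personal information, and drops those whose only "name" is an
    ambiguous anatomical word.  Order is preserved.
    """
    return [
        doc for doc in corpus
        if sum(1 for s in doc.spans if s.label == "NAME") >= min_count
    ]


def sample_fraction(
    corpus: Sequence[AnnotatedDocument], fraction: float, seed: int
) -> list[AnnotatedDocument]:
    """Uniformly sample ``floor(fraction * n)`` documents without
    replacement, deterministically; corpus order is preserved in the output."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    n = len(corpus)
    k = int(fraction * n)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=k, replace=False)) if k else []
    return [corpus[i] for i in idx]
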