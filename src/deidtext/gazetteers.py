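"""Weighted gazetteers: loading, sampling and dictionary matching.

Gazetteers are the lookup resources behind both pre-annotation (dictionary
matching of known names and hospital names in raw reports) and surrogate
generation (drawing a replacement name, municipality, institution or street
address).  Entries carry positive sampling weights — name frequencies for
person names, 2019 municipal populations for places — so surrogates follow
realistic marginal distributions.

The bundled miniature gazetteers under ``deidtext/data/gazetteers`` make the
package self-contained; they are small synthetic excerpts shaped like the
public Spanish registries (INE name/municipality lists, national hospital and
outpatient indices), not the registries themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
import numpy as np

from .corpus_io import EntitySpan, tokenize
from .errors import ExhaustionError, ParseError

__all__ = [
    "Gazetteer",
    "GazetteerSet",
    "load_gazetteer",
    "weighted_sample",
    "match_entities",
    "builtin_gazetteers",
]


@dataclass
class Gazetteer:
    """A category-labeled list of surfaces with positive sampling weights."""

    category: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for surface, weight in self.entries:
            if weight <= 0:
                raise ValueError(f"non-positive weight for {surface!r}")
            if surface in seen:
                raise ValueError(f"duplicate surface {surface!r}")
            seen.add(surface)

    @property
    def surfaces(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, w in self.entries))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GazetteerSet:
    """Category-keyed gazetteers for surrogate generation and pre-annotation.

    ``NAME``, ``LOC``, ``INST`` and ``DIR`` must be present for entity
    randomization.  ``given`` and ``surname`` are optional finer-grained
    name lists used to assemble multi-token person-name surrogates; when
    absent, multi-token names are drawn from the ``NAME`` gazetteer alone.
    """

    gazetteers: dict[str, Gazetteer]
    given: Gazetteer | None = None
    surname: Gazetteer | None = None

    def __getitem__(self, category: str) -> Gazetteer:
        return self.gazetteers[category]

    def __contains__(self, category: str) -> bool:
        return category in self.gazetteers

    def get(self, category: str) -> Gazetteer | None:
        return self.gazetteers.get(category)


def load_gazetteer(
    path: str | Path, category: str, min_weight: float = 0.0
) -> Gazetteer:
    """Load a ``surface<TAB>weight`` file into a :class:`Gazetteer`.

    ``#`` comment lines are ignored.  Duplicate surfaces are merged by
    summing their weights, then entries below ``min_weight`` are dropped
    (this mirrors frequency-threshold filtering of registry name lists,
    e.g. keeping only names with national frequency >= 20).
    """
    merged: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(
                    f"expected 'surface<TAB>weight', got {line!r}", line=lineno
                )
            surface, weight_str = cols[0].strip(), cols[1].strip()
            try:
                weight = float(weight_str)
            except ValueError:
                raise ParseError(
                    f"non-numeric weight {weight_str!r}", line=lineno
                ) from None
            if weight <= 0:
                raise ParseError(
                    f"non-positive weight {weight} for {surface!r}", line=lineno
                )
            merged[surface] = merged.get(surface, 0.0) + weight
    entries = [(s, w) for s, w in merged.items() if w >= min_weight]
    if not entries:
        import warnings

        warnings.warn(
            f"gazetteer {path} is empty after filtering (min_weight="
            f"{min_weight})", stacklevel=2,
        )
    return Gazetteer(category, entries)


def weighted_sample(
    gaz: Gazetteer, rng: np.random.Generator, exclude: set[str] = frozenset()
) -> str:
    """Draw one surface with probability proportional to its weight.

    Excluded surfaces are removed and the remaining weights renormalized
    (cumulative-weight inversion).  Raises :class:`ExhaustionError` when
    nothing is left to draw — the surrogate engine treats that as a signal
    to fall back to a generated replacement.
    """
    surfaces: list[str] = []
    weights: list[float] = []
    for surface, weight in gaz.entries:
        if surface not in exclude:
            surfaces.append(surface)
            weights.append(weight)
    if not surfaces:
        raise ExhaustionError(
            f"all {len(gaz)} entries of {gaz.category} gazetteer excluded"
        )
    cum = np.cumsum(weights)
    u = rng.random() * cum[-1]
    return surfaces[int(np.searchsorted(cum, u, side="right"))]


def _phrase_index(gaz: Gazetteer):
    """Index gazetteer surfaces by their first token (lowercased)."""
    index: dict[str, list[tuple[int, str, str]]] = {}
    for surface in gaz.surfaces:
        toks = tokenize(surface)
        if not toks:
            continue
        key = toks[0].text.lower()
        index.setdefault(key, []).append((len(toks), surface.lower(), surface))
    for cands in index.values():
        cands.sort(reverse=True)  # longest first
    return index


def match_entities(text: str, gaz: Gazetteer) -> list[EntitySpan]:
    """Find gazetteer surfaces in ``text`` as labeled spans.

    Matching is case-insensitive but accent-sensitive, anchored to token
    boundaries, longest-match-wins with a left-to-right greedy scan (so a
    full name outranks its component given name).  Returned spans never
    overlap.
    """
    tokens = tokenize(text)
    index = _phrase_index(gaz)
    spans: list[EntitySpan] = []
    i = 0
    while i < len(tokens):
        cands = index.get(tokens[i].text.lower())
        matched = False
        if cands:
            for n_toks, lower_surface, _surface in cands:
                j = i + n_toks - 1
                if j >= len(tokens):
                    continue
                start, end = tokens[i].start, tokens[j].end
                if text[start:end].lower() == lower_surface:
                    spans.append(
                        EntitySpan(start, end, gaz.category, text[start:end])
                    )
                    i = j + 1
                    matched = True
                    break
        if not matched:
            i += 1
    return spans


_DATA_PACKAGE = "deidtext.data.gazetteers"

_BUILTIN_FILES = {
    "LOC": "loc.tsv",
    "INST": "inst.tsv",
    "DIR": "dir.tsv",
}


def builtin_gazetteers(min_name_weight: float = 0.0) -> GazetteerSet:
    """Load the bundled miniature gazetteers shipped with the package.

    The NAME gazetteer is the union of the given-name and surname lists;
    both components are also exposed separately for multi-token name
    surrogate assembly.
    """
    root = resources.files(_DATA_PACKAGE)
    with resources.as_file(root) as base:
        given = load_gazetteer(base / "given.tsv", "NAME", min_name_weight)
        surname = load_gazetteer(base / "surname.tsv", "NAME", min_name_weight)
        merged: dict[str, float] = {}
        for surface, weight in given.entries + surname.entries:
            merged[surface] = merged.get(surface, 0.0) + weight
        name = Gazetteer("NAME", sorted(merged.items()))
        gazetteers = {"NAME": name}
        for category, fname in _BUILTIN_FILES.items():
            gazetteers[category] = load_gazetteer(base / fname, category)
        # hospitals and outpatient clinics are separate indices on disk but
        # one INST category for tagging
        clinics = load_gazetteer(base / "clinic.tsv", "INST")
        inst_merged: dict[str, float] = {
            s: w for s, w in gazetteers["INST"].entries
        }
        for surface, weight in clinics.entries:
            inst_merged[surface] = inst_merged.get(surface, 0.0) + weight
        gazetteers["INST"] = Gazetteer("INST", sorted(inst_merged.items()))
    return GazetteerSet(gazetteers, given=given, surname=surname)


def gazetteer_set_from_directory(
    directory: str | Path, min_weight: float = 0.0
) -> GazetteerSet:
    """Build a :class:`GazetteerSet` from ``name.tsv``, ``loc.tsv``,
    ``inst.tsv`` and ``dir.tsv`` in ``directory``; missing files are skipped.
    Optional ``given.tsv`` / ``surname.tsv`` refine name surrogates."""
    directory = Path(directory)
    gazetteers: dict[str, Gazetteer] = {}
    for category, fname in [
        ("NAME", "name.tsv"), ("LOC", "loc.tsv"),
        ("INST", "inst.tsv"), ("DIR", "dir.tsv"),
    ]:
        p = directory / fname
        if p.exists():
            gazetteers[category] = load_gazetteer(p, category, min_weight)
    given = surname = None
    if (directory / "given.tsv").exists():
        given = load_gazetteer(directory / "given.tsv", "NAME", min_weight)
    if (directory / "surname.tsv").exists():
        surname = load_gazetteer(directory / "surname.tsv", "NAME", min_weight)
    return GazetteerSet(gazetteers, given=given, surname=surname)
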