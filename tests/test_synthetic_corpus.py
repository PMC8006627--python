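import calendar
import re

import numpy as np
import pytest

import deidtext as dt
from deidtext.errors import ConfigurationError
from deidtext.synthetic_corpus import (
    PROFILES,
    TEST_TARGET,
    annotated_token_shares,
    random_code,
    random_date,
    random_name,
)

_MONTH_NAMES = ("enero", "febrero", "marzo", "abril", "mayo", "junio",
                "julio", "agosto", "septiembre", "octubre", "noviembre",
                "diciembre")


def _date_is_valid(surface: str) -> bool:
    """Independent check that a date surface is a real calendar date."""
    m = re.fullmatch(r"(\d{2})([/-])(\d{2})\2(\d{4})", surface)
    if m:
        day, month, year = int(m.group(1)), int(m.group(3)), int(m.group(4))
    else:
        m = re.fullmatch(r"(\d{1,2}) de (\w+) de (\d{4})", surface)
        if not m or m.group(2) not in _MONTH_NAMES:
            return False
        day, year = int(m.group(1)), int(m.group(3))
        month = _MONTH_NAMES.index(m.group(2)) + 1
    if not (1 <= month <= 12):
        return False
    return 1 <= day <= calendar.monthrange(year, month)[1]


_CODE_RE = re.compile(r"[A-Z]?\d+(-\d+)?[A-Z]?")


class TestSurfaceGenerators:
    def test_dates_always_valid(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            assert _date_is_valid(random_date(rng))

    def test_codes_match_grammar(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            code = random_code(rng)
            assert _CODE_RE.fullmatch(code), code
            assert 3 <= sum(c.isdigit() for c in code) <= 10

    def test_names_have_requested_token_count(self, gazetteers):
        rng = np.random.default_rng(0)
        for k in (1, 2, 3):
            # whitespace parts; multi-word given names may add more
            name = random_name(gazetteers, rng, n_tokens=k)
            assert len(name.split()) >= k


class TestGenerateDocument:
    def test_cab_spans_cover_header_lines(self, gazetteers):
        doc = dt.generate_document(PROFILES["headered"], gazetteers,
                                   np.random.default_rng(3))
        header_surfaces = {h + ":" for h in PROFILES["headered"].header_labels}
        cab = [s for s in doc.spans if s.label == "CAB"]
        assert cab, "headered document should contain header spans"
        for s in cab:
            assert s.surface in header_surfaces

    def test_dept7_always_has_orphan_entity_line(self, gazetteers):
        profile = dt.StructureProfile(
            "dept7", PROFILES["dept7"].header_labels,
            orphan_entity_rate=1.0, ambiguity_rate=0.0, language="va",
        )
        for seed in range(5):
            doc = dt.generate_document(profile, gazetteers,
                                       np.random.default_rng(seed))
            lines = doc.text.split("\n")
            orphans = [
                s for s in doc.spans
                if s.label != "CAB" and s.surface in lines
            ]
            assert orphans

    def test_ambiguous_anatomical_token_tagged_outside(self, gazetteers):
        profile = dt.StructureProfile(
            "headered", PROFILES["headered"].header_labels,
            orphan_entity_rate=0.0, ambiguity_rate=1.0,
        )
        doc = dt.generate_document(profile, gazetteers,
                                   np.random.default_rng(0))
        occurrences = [m.start() for m in re.finditer("cabeza", doc.text)]
        assert occurrences
        for pos in occurrences:  # never inside an entity span
            assert not any(s.start <= pos < s.end for s in doc.spans)

    def test_meddocan_entities_follow_descriptors(self, gazetteers):
        doc = dt.generate_document(PROFILES["meddocan"], gazetteers,
                                   np.random.default_rng(1))
        spans = list(doc.spans)
        non_cab = [s for s in spans if s.label != "CAB"]
        assert non_cab
        for s in non_cab:
            # the annotation preceding a value on its line is a descriptor
            before = [c for c in spans if c.label == "CAB" and c.end < s.start]
            assert before and doc.text[before[-1].end:s.start] == " "

    def test_department_markers(self, gazetteers):
        rng = np.random.default_rng(2)
        d7 = dt.generate_document(PROFILES["dept7"], gazetteers, rng)
        dh = dt.generate_document(PROFILES["headered"], gazetteers, rng)
        assert d7.document.department == 7
        assert dh.document.department in set(range(1, 18)) - {7}


class TestGenerateCorpus:
    def test_empty(self, gazetteers):
        assert dt.generate_corpus(0, {"headered": 1.0}, dt.TRAIN_TARGET,
                                  gazetteers, np.random.default_rng(0)) == []

    def test_deterministic(self, gazetteers):
        mk = lambda: dt.generate_corpus(
            15, {"headered": 0.6, "dept7": 0.4}, dt.TRAIN_TARGET, gazetteers,
            np.random.default_rng(9))
        a, b = mk(), mk()
        assert [d.text for d in a] == [d.text for d in b]
        assert [d.spans for d in a] == [d.spans for d in b]

    def test_share_convergence_large_corpus(self, gazetteers):
        """At 1000 documents every category share sits within 2 percentage
        points of its target."""
        corpus = dt.generate_corpus(
            1000, {"headered": 0.85, "dept7": 0.15}, dt.TRAIN_TARGET,
            gazetteers, np.random.default_rng(5))
        shares = annotated_token_shares(corpus)
        for label, target in dt.TRAIN_TARGET.shares.items():
            assert abs(shares[label] - target) <= 2.0, label

    def test_profile_target_override(self, gazetteers):
        corpus = dt.generate_corpus(
            200, {"dept7": 1.0}, dt.TRAIN_TARGET, gazetteers,
            np.random.default_rng(6), profile_targets={"dept7": TEST_TARGET})
        shares = annotated_token_shares(corpus)
        # the override shifts the mix: institutions and addresses up,
        # headers far below the training-profile share (a structural floor
        # of forced header lines keeps CAB slightly above its target)
        assert abs(shares["INST"] - TEST_TARGET.shares["INST"]) <= 3.0
        assert abs(shares["DIR"] - TEST_TARGET.shares["DIR"]) <= 3.0
        assert shares["CAB"] < 15.0

    def test_bad_mix_rejected(self, gazetteers):
        with pytest.raises(ConfigurationError):
            dt.generate_corpus(5, {"headered": 0.5}, dt.TRAIN_TARGET,
                               gazetteers, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            dt.generate_corpus(5, {"nope": 1.0}, dt.TRAIN_TARGET,
                               gazetteers, np.random.default_rng(0))

    def test_target_shares_validated(self):
        with pytest.raises(ConfigurationError):
            dt.DistributionTarget({"NAME": 50.0})  # does not sum to 100
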