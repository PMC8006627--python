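import numpy as np
import pytest

import deidtext as dt
from deidtext.corpus_io import (
    NEWLINE_TOKEN,
    repair_bio,
    split_by_lines,
    split_corpus,
)
from deidtext.errors import (
    BoundaryMismatchError,
    IntegrityError,
    ParseError,
    SizingError,
)


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("", []),
        ("TAC craneal: sin hallazgos.",
         [("TAC", 0, 3), ("craneal", 4, 11), (":", 11, 12), ("sin", 13, 16),
          ("hallazgos", 17, 26), (".", 26, 27)]),
        ("14/03/2018", [("14/03/2018", 0, 10)]),
        ("3 de mayo de 1999",
         [("3", 0, 1), ("de", 2, 4), ("mayo", 5, 9), ("de", 10, 12),
          ("1999", 13, 17)]),
        ("(1234-AB).", [("(", 0, 1), ("1234-AB", 1, 8), (")", 8, 9),
                        (".", 9, 10)]),
    ])
    def test_examples(self, text, expected):
        toks = dt.tokenize(text)
        assert [(t.text, t.start, t.end) for t in toks] == expected

    def test_offsets_index_original_text(self, small_corpus):
        for doc in small_corpus[:10]:
            for tok in dt.tokenize(doc.text):
                assert doc.text[tok.start:tok.end] == tok.text
                assert "\n" not in tok.text

    def test_tokens_partition_non_whitespace(self, small_corpus):
        """Concatenating token slices plus inter-token gaps rebuilds the
        text; the gaps are pure whitespace."""
        for doc in small_corpus[:10]:
            toks = dt.tokenize(doc.text)
            pos = 0
            rebuilt = []
            for t in toks:
                gap = doc.text[pos:t.start]
                assert gap.strip() == ""
                rebuilt.append(gap + t.text)
                pos = t.end
            rebuilt.append(doc.text[pos:])
            assert "".join(rebuilt) == doc.text


class TestBioConversion:
    def test_no_spans_all_outside(self):
        doc = dt.AnnotatedDocument(dt.Document("d", "sin hallazgos"))
        seq = dt.spans_to_bio(doc)
        assert all(t == "O" for t in seq.tags)

    def test_two_token_span_tags(self):
        text = "María Pérez"
        doc = dt.AnnotatedDocument(
            dt.Document("d", text),
            (dt.EntitySpan(0, 11, "NAME", text),),
        )
        assert dt.spans_to_bio(doc).tags == ("B-NAME", "I-NAME")

    def test_span_crossing_token_boundary_rejected(self):
        text = "hallazgos"
        doc = dt.AnnotatedDocument(
            dt.Document("d", text), (dt.EntitySpan(0, 4, "NAME", "hall"),)
        )
        with pytest.raises(BoundaryMismatchError):
            dt.spans_to_bio(doc)

    def test_inverse_on_valid_input(self):
        text = "María Pérez"
        seq = dt.TaggedSequence(
            tuple(dt.tokenize(text)), ("B-NAME", "I-NAME")
        )
        spans = dt.bio_to_spans(seq, text)
        assert spans == [dt.EntitySpan(0, 11, "NAME", text)]

    def test_dangling_inside_tag_repaired(self):
        text = "el 14/03/2018"
        seq = dt.TaggedSequence(tuple(dt.tokenize(text)), ("O", "I-FECHA"))
        spans = dt.bio_to_spans(seq, text)
        assert spans == [dt.EntitySpan(3, 13, "FECHA", "14/03/2018")]

    def test_repair_keeps_valid_sequences(self):
        tags = ["B-NAME", "I-NAME", "O", "B-NUM"]
        assert repair_bio(tags) == tags

    def test_roundtrip_identity_on_generated_documents(self, small_corpus):
        for doc in small_corpus:
            seq = dt.spans_to_bio(doc)
            assert dt.bio_to_spans(seq, doc.text) == list(doc.spans)

    def test_split_by_lines_preserves_tokens(self, small_corpus):
        doc = small_corpus[0]
        seq = dt.spans_to_bio(doc)
        lines = split_by_lines(seq, doc.text)
        flat = [t for ln in lines for t in ln.tokens]
        assert flat == list(seq.tokens)
        for ln in lines:  # no line break inside a line-scoped sequence
            lo, hi = ln.tokens[0].start, ln.tokens[-1].end
            assert "\n" not in doc.text[lo:hi]


class TestConll:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.conll"
        p.write_text("", encoding="utf-8")
        assert dt.read_conll(p) == []

    def test_roundtrip(self, tmp_path, small_corpus):
        p = tmp_path / "c.conll"
        dt.write_conll(small_corpus, p)
        back = dt.read_conll(p)
        assert len(back) == len(small_corpus)
        for a, b in zip(small_corpus, back):
            assert a.id == b.id
            assert a.document.department == b.document.department
            sa, sb = dt.spans_to_bio(a), dt.spans_to_bio(b)
            assert [t.text for t in sa.tokens] == [t.text for t in sb.tokens]
            assert sa.tags == sb.tags
        # second round trip is the identity on bytes
        p2 = tmp_path / "c2.conll"
        dt.write_conll(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_blank_line_structure_survives(self, tmp_path):
        text = "INFORME:\n\nMaría"
        doc = dt.AnnotatedDocument(
            dt.Document("d1", text, 3),
            (dt.EntitySpan(10, 15, "NAME", "María"),),
        )
        p = tmp_path / "nl.conll"
        dt.write_conll([doc], p)
        assert NEWLINE_TOKEN in p.read_text(encoding="utf-8")
        back = dt.read_conll(p)[0]
        # reconstruction is whitespace-normalized (tokens single-space
        # joined) but the empty line survives
        assert back.text == "INFORME :\n\nMaría"

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.conll"
        p.write_text("-DOCSTART-\tO\t# id=d dept=1\nMaría B-NAME I-NAME\n",
                     encoding="utf-8")
        with pytest.raises(ParseError) as err:
            dt.read_conll(p)
        assert err.value.line == 2

    def test_unknown_tag_rejected(self, tmp_path):
        p = tmp_path / "bad.conll"
        p.write_text("María\tB-PERSON\n", encoding="utf-8")
        with pytest.raises(ParseError):
            dt.read_conll(p)


class TestBrat:
    def test_roundtrip(self, tmp_path, small_corpus):
        for doc in small_corpus[:5]:
            txt, ann = dt.write_brat(doc, tmp_path)
            back = dt.read_brat(txt, ann)
            assert back.text == doc.text
            assert list(back.spans) == list(doc.spans)

    def test_empty_annotations(self, tmp_path):
        (tmp_path / "d.txt").write_text("hola", encoding="utf-8")
        (tmp_path / "d.ann").write_text("", encoding="utf-8")
        doc = dt.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")
        assert doc.spans == ()

    def test_surface_mismatch_names_annotation(self, tmp_path):
        (tmp_path / "d.txt").write_text("consulta María López",
                                        encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tNAME 9 14\tPedro\n",
                                        encoding="utf-8")
        with pytest.raises(IntegrityError, match="T1"):
            dt.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")


def _dummy_corpus(n, n_dept7):
    docs = []
    for i in range(n):
        dept = 7 if i < n_dept7 else 1 + (i % 6)
        docs.append(dt.AnnotatedDocument(
            dt.Document(f"doc{i:04d}", "informe sin hallazgos", dept)
        ))
    return docs


class TestSplitCorpus:
    def test_reference_sizes_and_partition(self):
        corpus = _dummy_corpus(692, 97)
        split = split_corpus(corpus, 7, 65, (447, 213, 32), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) \
            == (447, 213, 32)
        ids = [d.id for part in (split.train, split.validation, split.test)
               for d in part]
        assert sorted(ids) == sorted(d.id for d in corpus)
        assert all(d.document.department == 7 for d in split.test)
        assert all(d.document.department != 7 for d in split.validation)
        n7_train = sum(1 for d in split.train if d.document.department == 7)
        assert n7_train == 65

    def test_degenerate_empty_heldout(self):
        corpus = _dummy_corpus(10, 0)
        split = split_corpus(corpus, 7, 0, (7, 3, 0), seed=1)
        assert len(split.test) == 0 and len(split.train) == 7

    def test_deterministic_given_seed(self):
        corpus = _dummy_corpus(100, 20)
        a = split_corpus(corpus, 7, 10, (60, 30, 10), seed=5)
        b = split_corpus(corpus, 7, 10, (60, 30, 10), seed=5)
        assert [d.id for d in a.train] == [d.id for d in b.train]
        assert [d.id for d in a.test] == [d.id for d in b.test]

    def test_insufficient_heldout_errors(self):
        corpus = _dummy_corpus(100, 5)
        with pytest.raises(SizingError):
            split_corpus(corpus, 7, 10, (60, 30, 10), seed=0)
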