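import numpy as np
import pytest

import deidtext as dt
from deidtext.errors import AlignmentError
from deidtext.evaluation import (
    ConfusionCounts,
    EvalReport,
    evaluate_corpus,
    evaluate_pairs,
    global_deid,
    prf,
    token_confusion,
)


def _seq(words, tags):
    text = " ".join(words)
    return dt.TaggedSequence(tuple(dt.tokenize(text)), tuple(tags))


class TestPrf:
    def test_reference_arithmetic(self):
        p = prf(3, 1, 2)
        assert (p.precision, p.recall) == (0.75, 0.6)
        assert abs(p.f1 - 0.6667) < 5e-5
        assert not p.degenerate

    def test_degenerate_convention(self):
        p = prf(0, 0, 0)
        assert (p.precision, p.recall, p.f1) == (0, 0, 0) and p.degenerate

    def test_perfect(self):
        assert prf(5, 0, 0)[:3] == (1.0, 1.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(-1, 0, 0)

    def test_agrees_with_sklearn(self):
        """Cross-check against an independent metric implementation on 100
        random count triples."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fp, fn = (int(x) for x in rng.integers(0, 20, size=3))
            if tp + fp == 0 or tp + fn == 0:
                continue
            y_true = [1] * tp + [1] * fn + [0] * fp
            y_pred = [1] * tp + [0] * fn + [1] * fp
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="binary", zero_division=0
            )
            ours = prf(tp, fp, fn)
            assert abs(ours.precision - p) < 1e-12
            assert abs(ours.recall - r) < 1e-12
            assert abs(ours.f1 - f) < 1e-12


class TestTokenConfusion:
    def test_identical_sequences(self):
        g = _seq(["María", "hoy"], ["B-NAME", "O"])
        c = token_confusion(g, g)
        assert c.per_category["NAME"] == [1, 0, 0]
        assert all(c.per_category[lab][1:] == [0, 0]
                   for lab in dt.ENTITY_LABELS)
        assert c.binary == [1, 0, 0]

    def test_cross_category_detection_counts_binary_tp(self):
        g = _seq(["María", "hoy"], ["B-NAME", "O"])
        p = _seq(["María", "hoy"], ["B-FECHA", "O"])
        c = token_confusion(g, p)
        assert c.per_category["NAME"] == [0, 0, 1]   # category FN
        assert c.per_category["FECHA"] == [0, 1, 0]  # category FP
        assert c.binary == [1, 0, 0]                 # still removed

    def test_headers_are_not_identifying(self):
        g = _seq(["INFORME:"], ["B-CAB", "I-CAB"])  # two tokens: word + colon
        p = _seq(["INFORME:"], ["O", "O"])
        c = token_confusion(g, p)
        assert c.per_category["CAB"] == [0, 0, 2]
        assert c.binary == [0, 0, 0]

    def test_misaligned_tokens_rejected(self):
        with pytest.raises(AlignmentError):
            token_confusion(_seq(["a"], ["O"]), _seq(["b"], ["O"]))

    def test_conservation_per_category(self, small_corpus):
        """TP + FN equals the number of gold tokens of each category, and
        binary TP is at least the sum of category TPs."""
        rng = np.random.default_rng(0)
        for doc in small_corpus[:10]:
            gold = dt.spans_to_bio(doc)
            # perturb ~20% of predicted tags
            tags = list(gold.tags)
            for i in range(len(tags)):
                if rng.random() < 0.2:
                    tags[i] = "B-FECHA" if tags[i] == "O" else "O"
            pred = dt.TaggedSequence(gold.tokens, tuple(tags))
            c = token_confusion(gold, pred)
            for lab in dt.ENTITY_LABELS:
                gold_count = sum(
                    1 for t in gold.tags if t.endswith(f"-{lab}")
                )
                assert c.per_category[lab][0] + c.per_category[lab][2] \
                    == gold_count
            assert c.binary[0] >= sum(
                c.per_category[lab][0] for lab in dt.IDENTIFYING_LABELS
            )


class TestGlobalDeid:
    def test_perfect_prediction(self):
        g = _seq(["María", "12345678"], ["B-NAME", "B-NUM"])
        assert global_deid(g, g)[:3] == (1.0, 1.0, 1.0)

    def test_nine_of_ten_with_one_spurious(self):
        words = [f"w{i}" for i in range(12)]
        gold = ["B-NAME"] * 10 + ["O", "O"]
        pred = ["B-NAME"] * 5 + ["B-NUM"] * 4 + ["O", "B-FECHA", "O"]
        m = global_deid(_seq(words, gold), _seq(words, pred))
        assert m.recall == 0.9 and m.precision == 0.9

    def test_all_outside_prediction_degenerate(self):
        g = _seq(["María"], ["B-NAME"])
        p = _seq(["María"], ["O"])
        m = global_deid(g, p)
        assert m.recall == 0.0 and m.precision == 0.0 and m.degenerate


class TestMicroAveraging:
    def test_pooled_counts(self):
        a_gold = _seq(["Ana", "Luz"], ["B-NAME", "B-NAME"])
        a_pred = _seq(["Ana", "Luz"], ["B-NAME", "O"])   # (1, 0, 1)
        b_gold = _seq(["Pau", "x"], ["B-NAME", "O"])
        b_pred = _seq(["Pau", "x"], ["B-NAME", "B-NAME"])  # (1, 1, 0)
        report = evaluate_pairs([(a_gold, a_pred), (b_gold, b_pred)])
        name = report.per_category["NAME"]
        assert abs(name.precision - 2 / 3) < 1e-12
        assert abs(name.recall - 2 / 3) < 1e-12

    def test_partition_additivity(self, small_corpus):
        pairs = []
        for doc in small_corpus[:8]:
            gold = dt.spans_to_bio(doc)
            pairs.append((gold, gold))
        whole = evaluate_pairs(pairs).counts
        first = evaluate_pairs(pairs[:4]).counts
        second = evaluate_pairs(pairs[4:]).counts
        merged = ConfusionCounts().merge(first).merge(second)
        assert merged.per_category == whole.per_category
        assert merged.binary == whole.binary


class TestStrictSpanMode:
    def test_exact_match_required(self):
        from deidtext.evaluation import strict_span_confusion

        text = "María García 12345678"
        gold = [dt.EntitySpan(0, 12, "NAME", "María García"),
                dt.EntitySpan(13, 21, "NUM", "12345678")]
        # boundary slip on the name (first token only), NUM exact
        pred = [dt.EntitySpan(0, 5, "NAME", "María"),
                dt.EntitySpan(13, 21, "NUM", "12345678")]
        c = strict_span_confusion(gold, pred)
        assert c.per_category["NAME"] == [0, 1, 1]
        assert c.per_category["NUM"] == [1, 0, 0]
        assert c.binary == [1, 1, 1]

    def test_perfect_agreement(self):
        from deidtext.evaluation import strict_span_confusion

        spans = [dt.EntitySpan(0, 5, "FECHA", "14/03")]
        c = strict_span_confusion(spans, spans)
        assert c.per_category["FECHA"] == [1, 0, 0]
        assert c.binary == [1, 0, 0]


class _EchoModel:
    """Predicts exactly the gold annotation (for report plumbing tests)."""

    def __init__(self, corpus):
        self._gold = {d.id: d for d in corpus}

    def predict_tagged(self, document):
        return dt.spans_to_bio(self._gold[document.id])


class TestEvalReport:
    def test_perfect_corpus_report(self, small_corpus):
        docs = small_corpus[:3]
        report = evaluate_corpus(_EchoModel(docs), docs)
        assert report.global_metrics[:3] == (1.0, 1.0, 1.0)

    def test_row_order_fixed(self, small_corpus):
        docs = small_corpus[:2]
        report = evaluate_corpus(_EchoModel(docs), docs)
        rows = [ln.split("\t")[0] for ln in report.render().splitlines()[1:]]
        assert rows == ["CAB", "NAME", "DIR", "LOC", "NUM", "FECHA", "INST",
                        "global"]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            evaluate_corpus(_EchoModel([]), [])
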