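import numpy as np
import pytest

import deidtext as dt
from deidtext.errors import ModelError
from deidtext.ner import _autograd as ag
from deidtext.ner.model import (
    ARCHITECTURES,
    ModelConfig,
    TrainedModel,
    apply_ema,
    forward_emissions,
    init_parameters,
    parameter_count,
)
from deidtext.ner.vocab import TAG_INVENTORY, Vocabulary

from conftest import make_overfit_sequence, overfit_nll


def _tiny_model(architecture="lstm-crf", seed=0, corpus_seq=None):
    seq = corpus_seq or dt.spans_to_bio(make_overfit_sequence())
    config = ModelConfig(architecture=architecture, word_dim=8, char_dim=4,
                         char_hidden=4, word_hidden=8, dropout=0.0, seed=seed)
    vocab = Vocabulary.build([seq])
    params = init_parameters(config, vocab, np.random.default_rng(seed))
    return TrainedModel(config=config, vocab=vocab, params=params)


class TestVocabulary:
    def test_tag_inventory_complete(self):
        assert len(TAG_INVENTORY) == 1 + 2 * len(dt.ENTITY_LABELS)
        assert TAG_INVENTORY[0] == "O"

    def test_unknown_word_maps_to_unk(self):
        vocab = Vocabulary.build([dt.spans_to_bio(make_overfit_sequence())])
        assert vocab.word_id("palabrainventada") == vocab.words["<unk>"]
        assert vocab.word_id("María") == vocab.word_id("MARÍA")  # lowercased


class TestEncodeTokens:
    def test_zero_projection_gives_zero_emissions(self):
        model = _tiny_model()
        model.params["proj_w"][:] = 0.0
        model.params["proj_b"][:] = 0.0
        seq = dt.spans_to_bio(make_overfit_sequence())
        assert np.all(model.encode_tokens(seq) == 0.0)

    def test_deterministic(self):
        model = _tiny_model("conv-lstm-crf")
        seq = dt.spans_to_bio(make_overfit_sequence())
        a, b = model.encode_tokens(seq), model.encode_tokens(seq)
        assert np.array_equal(a, b)

    def test_distinct_oov_words_equivalent_without_char_channel(self):
        """Two sequences differing only in two different OOV words produce
        identical emissions for the word-only architecture (both collapse to
        the UNK embedding)."""
        model = _tiny_model("lstm-crf")
        mk = lambda w: dt.TaggedSequence(
            tuple(dt.tokenize(f"informe de {w} hoy")), ("O",) * 4
        )
        a = model.encode_tokens(mk("zzyzx"))
        b = model.encode_tokens(mk("qwrty"))
        assert np.allclose(a, b)

    def test_char_channel_distinguishes_oov_words(self):
        model = _tiny_model("lstm-lstm-crf")
        mk = lambda w: dt.TaggedSequence(
            tuple(dt.tokenize(f"informe de {w} hoy")), ("O",) * 4
        )
        assert not np.allclose(model.encode_tokens(mk("zzyzx")),
                               model.encode_tokens(mk("qwrty")))

    def test_empty_sequence_rejected(self):
        model = _tiny_model()
        with pytest.raises(ModelError):
            model.encode_tokens(dt.TaggedSequence((), ()))


class TestEma:
    def test_zero_decay_copies_current(self):
        shadow = {"w": np.zeros(3)}
        current = {"w": np.ones(3)}
        assert np.array_equal(apply_ema(shadow, current, 0.0)["w"],
                              current["w"])

    def test_fixed_point(self):
        shadow = {"w": np.full(3, 2.0)}
        out = apply_ema(shadow, {"w": np.full(3, 2.0)}, 0.9)
        assert np.array_equal(out["w"], shadow["w"])

    def test_two_updates_closed_form(self):
        """shadow_0 = 0, current = 1, decay 0.9: after t updates the shadow
        is 1 - decay^t; at t = 2 that is 0.19."""
        shadow = {"w": np.zeros(1)}
        for _ in range(2):
            shadow = apply_ema(shadow, {"w": np.ones(1)}, 0.9)
        assert np.allclose(shadow["w"], 0.19)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ModelError):
            apply_ema({"w": np.zeros(3)}, {"w": np.zeros(4)}, 0.9)
        with pytest.raises(ModelError):
            apply_ema({"w": np.zeros(3)}, {"v": np.zeros(3)}, 0.9)


class TestParameterAccounting:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_count_matches_closed_form(self, arch):
        model = _tiny_model(arch)
        assert model.parameter_count() == parameter_count(model.config,
                                                          model.vocab)

    def test_char_settings_ignored_without_char_channel(self):
        a = _tiny_model("lstm-crf")
        assert not any(k.startswith("char") for k in a.params)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        model = _tiny_model("lstm-lstm-crf")
        model.ema = {k: v.copy() for k, v in model.params.items()}
        model.save(tmp_path / "ckpt")
        back = TrainedModel.load(tmp_path / "ckpt")
        doc = make_overfit_sequence().document
        assert back.predict(doc) == model.predict(doc)
        assert back.config == model.config

    def test_corrupt_checkpoint_detected(self, tmp_path):
        model = _tiny_model()
        model.save(tmp_path / "ckpt")
        # shrink the stored vocabulary: parameter shapes no longer match
        import json
        vpath = tmp_path / "ckpt" / "vocab.json"
        vdata = json.loads(vpath.read_text(encoding="utf-8"))
        vdata["words"] = {"<pad>": 0, "<unk>": 1}
        vpath.write_text(json.dumps(vdata), encoding="utf-8")
        with pytest.raises(ModelError):
            TrainedModel.load(tmp_path / "ckpt")


class TestSingleSequenceOverfit:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_nll_below_threshold_within_200_steps(self, arch):
        nll, steps = overfit_nll(arch)
        assert nll < 0.1, f"{arch}: NLL {nll} after {steps} steps"


class TestPretrainedEmbeddings:
    def test_rows_loaded_and_dimension_checked(self, tmp_path):
        from deidtext.ner.model import load_pretrained_embeddings

        seq = dt.spans_to_bio(make_overfit_sequence())
        vocab = Vocabulary.build([seq])
        emb = np.zeros((vocab.n_words, 3))
        p = tmp_path / "vecs.txt"
        p.write_text("maría 1.0 2.0 3.0\ndesconocida 4.0 5.0 6.0\n",
                     encoding="utf-8")
        loaded = load_pretrained_embeddings(p, vocab, emb)
        assert loaded == 1  # 'desconocida' is not in the vocabulary
        assert np.array_equal(emb[vocab.word_id("María")], [1.0, 2.0, 3.0])
        bad = tmp_path / "bad.txt"
        bad.write_text("maría 1.0 2.0\n", encoding="utf-8")
        with pytest.raises(ModelError):
            load_pretrained_embeddings(bad, vocab, emb)


class TestPredict:
    def test_empty_document(self):
        model = _tiny_model()
        assert model.predict(dt.Document("e", "")) == []

    def test_prediction_is_pure(self):
        model = _tiny_model("conv-lstm-crf")
        doc = make_overfit_sequence().document
        assert model.predict(doc) == model.predict(doc)
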