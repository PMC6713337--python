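"""SDP-CNN: initialization, forward pass, training, CV mechanics."""

import numpy as np
import pytest

from pdrelex import cnn
from pdrelex.cnn import (
    EmbeddingConfig,
    ModelConfig,
    Vocabulary,
    cross_validate,
    init_model,
    predict,
    relabel_binary,
    train,
)
from pdrelex.sdp import RelationInstance


def toy_instance(tokens, label="ToD", doc_id="d1"):
    n = len(tokens)
    return RelationInstance(
        doc_id=doc_id,
        tokens=tuple(tokens),
        pos_tags=("NOUN",) * n,
        p1_indices=tuple(range(30, 30 + n)),
        p2_indices=tuple(range(30, 30 + n)),
        sdp=None,
        left_tokens=tuple(tokens[:2]),
        left_pos=("NOUN",) * min(2, n),
        left_p1=(30,) * min(2, n),
        left_p2=(30,) * min(2, n),
        right_tokens=tuple(tokens[-2:]),
        right_pos=("NOUN",) * min(2, n),
        right_p1=(30,) * min(2, n),
        right_p2=(30,) * min(2, n),
        label=label,
    )


SMALL_M = ModelConfig(filters_per_window=4, epochs=3, seed=0)
SMALL_E = EmbeddingConfig(word_dim=8, pe_dim=3, pos_dim=3)


@pytest.fixture()
def toy_batch():
    words = ["alpha", "beta", "gamma", "delta", "epsilon"]
    return [
        toy_instance(words[: 2 + i % 4], label=("ToD" if i % 2 else "Negative"))
        for i in range(8)
    ]


class TestInit:
    def test_default_hyperparameters(self):
        cfg = ModelConfig()
        assert cfg.filter_windows == (3, 4, 5)
        assert cfg.dropout == 0.5
        assert len(cfg.labels) == 4

    def test_same_seed_identical_parameters(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        a = init_model(SMALL_M, SMALL_E, vocab)
        b = init_model(SMALL_M, SMALL_E, vocab)
        assert set(a.params) == set(b.params)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_pretrained_rows_copied_and_oov_counted(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        pretrained = {
            "alpha": np.full(SMALL_E.word_dim, 0.5),
            "beta": np.full(SMALL_E.word_dim, -0.5),
            "notinvocab": np.zeros(SMALL_E.word_dim),
        }
        model = init_model(SMALL_M, SMALL_E, vocab, pretrained=pretrained)
        hits = sum(
            np.array_equal(model.params["E_word"][i], pretrained[w])
            for w, i in vocab.word2id.items()
            if w in pretrained
        )
        assert hits == 2  # |vocab ∩ pretrained|
        oov = len(vocab.word2id) - hits
        assert oov == len(vocab.word2id) - 2

    def test_pretrained_dimension_mismatch_rejected(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        with pytest.raises(ValueError, match="dimension"):
            init_model(SMALL_M, SMALL_E, vocab, pretrained={"alpha": np.zeros(99)})

    def test_channel_ablations_shrink_parameter_count(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        full = init_model(SMALL_M, SMALL_E, vocab)
        sdp_only = init_model(
            ModelConfig(
                filters_per_window=4, epochs=3, seed=0, channels="sdp_only"
            ),
            SMALL_E,
            vocab,
        )
        n = lambda m: sum(v.size for v in m.params.values())
        assert n(full) > n(sdp_only)


class TestForward:
    def test_softmax_outputs_normalized(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        model = init_model(SMALL_M, SMALL_E, vocab)
        probs, _ = predict(model, toy_batch)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_evaluation_forward_deterministic(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        model = init_model(SMALL_M, SMALL_E, vocab)
        p1, _ = predict(model, toy_batch)
        p2, _ = predict(model, toy_batch)
        np.testing.assert_array_equal(p1, p2)

    def test_sequence_shorter_than_window_is_padded(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        model = init_model(SMALL_M, SMALL_E, vocab)
        short = [toy_instance(["alpha"], label="ToD")]
        probs, _ = predict(model, short)
        assert probs.shape == (1, 4)
        assert np.isfinite(probs).all()

    def test_max_pool_matches_bruteforce_single_filter(self, toy_batch):
        """Pooled value equals the max over all window positions."""
        from pdrelex.cnn import _forward

        mcfg = ModelConfig(filters_per_window=1, filter_windows=(2,), dropout=0.0, seed=1)
        vocab = Vocabulary.build(toy_batch, 30)
        model = init_model(mcfg, SMALL_E, vocab)
        inst = toy_batch[3]  # 5 sentence tokens
        enc = model.encode(inst)
        probs, cache = _forward(model, [enc], train_mode=False)
        p = model.params
        ids = enc["sentence"]
        X = np.concatenate(
            [
                p["E_word"][ids[0]],
                p["E_p1"][ids[1]],
                p["E_p2"][ids[2]],
                p["E_pos"][ids[3]],
            ],
            axis=1,
        )
        W, b = p["W_sentence_2"], p["b_sentence_2"]
        manual = max(
            max(0.0, float(X[i : i + 2].ravel() @ W[0] + b[0]))
            for i in range(X.shape[0] - 1)
        )
        pooled = cache["channels"]["sentence"]["windows"][2]["pooled"][0, 0]
        assert pooled == pytest.approx(manual)


class TestTrain:
    def test_overfits_separable_cues(self):
        words = {"ToD": "reduced", "CoD": "induced", "Association": "linked",
                 "Negative": "unrelated"}
        insts = []
        for i in range(40):
            label = list(words)[i % 4]
            insts.append(
                toy_instance(["plant", words[label], "disease"], label=label, doc_id=f"d{i}")
            )
        vocab = Vocabulary.build(insts, 30)
        model = init_model(ModelConfig(filters_per_window=8, epochs=50, seed=0), SMALL_E, vocab)
        train(model, insts)
        _, pred = predict(model, insts)
        acc = np.mean([p == i.label for p, i in zip(pred, insts)])
        assert acc >= 0.95

    def test_loss_decreases_allowing_plateaus(self):
        insts = [
            toy_instance(["plant", w, "disease"], label=l, doc_id=f"d{i}")
            for i, (w, l) in enumerate(
                [("reduced", "ToD"), ("induced", "CoD")] * 10
            )
        ]
        vocab = Vocabulary.build(insts, 30)
        model = init_model(
            ModelConfig(filters_per_window=8, epochs=30, seed=0, batch_size=20),
            SMALL_E,
            vocab,
        )
        train(model, insts)
        hist = np.array(model.history)
        assert hist[-1] < hist[0]
        # downward trend overall; isolated small plateaus/bumps are fine
        slope = np.polyfit(np.arange(len(hist)), hist, 1)[0]
        assert slope < 0
        assert hist[-3:].mean() < hist[:3].mean()

    def test_static_mode_freezes_word_embeddings(self, toy_batch):
        vocab = Vocabulary.build(toy_batch, 30)
        econfig = EmbeddingConfig(word_dim=8, pe_dim=3, pos_dim=3, static=True)
        model = init_model(SMALL_M, econfig, vocab)
        before = model.params["E_word"].copy()
        train(model, toy_batch)
        np.testing.assert_array_equal(model.params["E_word"], before)
        # but the position embeddings did move
        assert model.history  # training actually ran

    def test_single_class_data_rejected(self, toy_batch):
        only_tod = [i for i in toy_batch if i.label == "ToD"]
        vocab = Vocabulary.build(only_tod, 30)
        model = init_model(SMALL_M, SMALL_E, vocab)
        with pytest.raises(ValueError, match="two classes"):
            train(model, only_tod)


class TestRelabelBinary:
    def counts(self, instances):
        pos = sum(i.label == "Positive" for i in instances)
        return pos, len(instances) - pos

    def make(self):
        labels = ["ToD"] * 508 + ["CoD"] * 183 + ["Association"] * 34 + ["Negative"] * 584
        return [toy_instance(["x"], label=l) for l in labels]

    def test_tod_vs_rest(self):
        out = relabel_binary(self.make(), {"ToD"})
        assert self.counts(out) == (508, 801)

    def test_all_positive_types(self):
        out = relabel_binary(self.make(), {"ToD", "CoD", "Association"})
        assert self.counts(out) == (725, 584)

    def test_idempotent(self):
        once = relabel_binary(self.make(), {"ToD"})
        twice = relabel_binary(once, {"ToD"})
        assert [i.label for i in once] == [i.label for i in twice]

    def test_empty_positive_set_rejected(self):
        with pytest.raises(ValueError):
            relabel_binary(self.make(), set())


class TestCrossValidate:
    def test_folds_partition_documents(self, small_instances):
        subset = [i for i in small_instances if i.doc_id <= "10000020"]
        mcfg = ModelConfig(filters_per_window=4, epochs=2, seed=0)
        res = cross_validate(subset, mcfg, SMALL_E, folds=10)
        docs = {i.doc_id for i in subset}
        assert set(res.fold_assignment) == docs
        sizes = [list(res.fold_assignment.values()).count(f) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1
        assert len(res.predictions.y_true) == len(subset)

    def test_fewer_documents_than_folds_rejected(self, toy_batch):
        with pytest.raises(ValueError):
            cross_validate(toy_batch, SMALL_M, SMALL_E, folds=10)
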