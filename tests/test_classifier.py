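"""Input sequences, tokenization, training and prediction of the 5-class model."""

import numpy as np
import pytest

import goaqc
from goaqc import (
    CLASSES,
    Document,
    GeneProduct,
    GOAInstance,
    TrainingConfig,
    build_input_sequence,
    detokenize,
    predict_batch,
    tokenize,
    train_classifier,
)
from goaqc.classify import CLS, JOIN, PAD, SEP, load_model, save_model
from goaqc.errors import MissingDocumentError, TrainingError


def _inst(term="GO:0051592", symbol="Syt1", pmid="18508778"):
    return GOAInstance(GeneProduct(25716, symbol, 10116), term, pmid, "IDA", "CO")


class TestInputSequence:
    def test_template_order(self, fragment_dag):
        doc = Document("18508778", "T", "A")
        seq = build_input_sequence(_inst(), doc, fragment_dag, max_len=20)
        toks = [t for t in seq.tokens if t != PAD]
        assert toks == [CLS, "T", JOIN, "A", JOIN, "Syt1", SEP,
                        "response", "to", "calcium", "ion", SEP]
        assert seq.length == 20

    def test_long_abstract_truncated_to_350(self, fragment_dag):
        doc = Document("18508778", "short title", "word " * 3000)
        seq = build_input_sequence(_inst(), doc, fragment_dag)
        assert seq.length == 350
        # the decision-critical tail survives truncation
        assert list(seq.tokens[-6:]) == [SEP, "response", "to", "calcium", "ion", SEP]

    def test_empty_abstract_double_delimiter(self, fragment_dag):
        doc = Document("18508778", "T")
        seq = build_input_sequence(_inst(), doc, fragment_dag, max_len=20)
        toks = [t for t in seq.tokens if t != PAD]
        assert toks[:5] == [CLS, "T", JOIN, JOIN, "Syt1"]
        title, abstract, symbol, term = seq.segments()
        assert abstract == [] and symbol == ["Syt1"]

    def test_missing_doc_raises(self, fragment_dag):
        with pytest.raises(MissingDocumentError):
            build_input_sequence(_inst(), None, fragment_dag)


class TestTokenize:
    def test_wordpiece_oov_split(self):
        vocab = {"polyc", "##omb", "the"}
        assert tokenize("the polycomb", vocab) == ["the", "polyc", "##omb"]

    def test_empty_string(self):
        assert tokenize("", None) == []
        assert tokenize("", {"a"}) == []

    def test_roundtrip_property(self):
        from goaqc.classify import make_wordpiece_vocab

        rng = np.random.default_rng(0)
        alphabet = list("abcdefgh")
        corpus = [" ".join("".join(rng.choice(alphabet, size=rng.integers(1, 9)))
                           for _ in range(rng.integers(1, 12)))
                  for _ in range(100)]
        vocab = make_wordpiece_vocab(corpus[:50])  # half the words are OOV
        for text in corpus:
            assert detokenize(tokenize(text, vocab)) == " ".join(text.split())


@pytest.fixture(scope="module")
def trained_model(std_world, std_splits):
    train, dev, _ = std_splits
    return train_classifier(train, dev, std_world.dag, std_world.docs)


class TestTraining:
    def test_learns_on_high_signal_world(self, std_world, std_splits, trained_model):
        from goaqc.evaluation import metrics_table

        _, _, test = std_splits
        preds = [r.label for r in predict_batch(trained_model, test, std_world.docs,
                                                std_world.dag)]
        gold = [i.label for i in test]
        tab = metrics_table(preds, gold)
        macro = float(tab[tab["class"] == "macro"]["f1"].iloc[0])
        assert macro >= 0.6

    def test_dev_loss_logged(self, trained_model):
        assert len(trained_model.dev_loss_history) == trained_model.cfg.epochs

    def test_single_class_degenerates_with_warning(self, std_world, std_splits):
        train, _, _ = std_splits
        co_only = [i for i in train if i.label == "CO"][:64]
        with pytest.warns(UserWarning, match="single-class"):
            model = train_classifier(
                co_only, [], std_world.dag, std_world.docs,
                cfg=TrainingConfig(epochs=10, warmup_steps=0, learning_rate=5e-3))
        res = predict_batch(model, co_only[:5], std_world.docs, std_world.dag)
        assert all(r.label == "CO" for r in res)

    def test_zero_epochs_untrained(self, std_world, std_splits):
        train, _, _ = std_splits
        with pytest.warns(UserWarning, match="untrained"):
            model = train_classifier(train[:32], [], std_world.dag, std_world.docs,
                                     cfg=TrainingConfig(epochs=0))
        assert not model.trained


@pytest.fixture(scope="module")
def embeddings(std_world):
    from goaqc.specificity import (
        TrainingConfig as TC,
        build_edge_dataset,
        extract_embeddings,
        init_node_features,
        train_edge_classifier,
    )

    dag = std_world.dag
    feats = init_node_features(dag, "structural", d=24)
    edges = build_edge_dataset(dag, 0.74, np.random.default_rng(2))
    model = train_edge_classifier(dag, feats, edges,
                                  TC(epochs=25, batch_size=64, warmup_steps=50))
    return extract_embeddings(model, dag)


class TestFusion:
    def test_head_width_is_encoder_plus_embedding(self, std_world, std_splits,
                                                  embeddings):
        train, dev, _ = std_splits
        model = train_classifier(train[:200], [], std_world.dag, std_world.docs,
                                 embeddings=embeddings, cfg=TrainingConfig(epochs=1))
        d_in = model.head.layers[0].W.value.shape[0]
        assert d_in == model.encoder.dim + 24
        assert model.fusion

    def test_missing_embedding_names_term(self, std_world, std_splits, embeddings):
        train, _, _ = std_splits
        partial = dict(embeddings)
        partial.pop(train[0].term_id)
        with pytest.raises(TrainingError, match=train[0].term_id):
            train_classifier(train[:50], [], std_world.dag, std_world.docs,
                             embeddings=partial, cfg=TrainingConfig(epochs=1))


class TestPrediction:
    def test_probability_simplex_and_entropy_bound(self, std_world, std_splits,
                                                   trained_model):
        _, _, test = std_splits
        for r in predict_batch(trained_model, test[:100], std_world.docs, std_world.dag):
            assert r.probs.shape == (5,)
            assert r.probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert 0.0 <= r.tau <= np.log2(5) + 1e-9
            assert r.label == CLASSES[int(np.argmax(r.probs))]

    def test_prediction_deterministic(self, std_world, std_splits, trained_model):
        _, _, test = std_splits
        a = predict_batch(trained_model, test[:20], std_world.docs, std_world.dag)
        b = predict_batch(trained_model, test[:20], std_world.docs, std_world.dag)
        assert [r.label for r in a] == [r.label for r in b]
        assert all(np.array_equal(x.probs, y.probs) for x, y in zip(a, b))

    def test_save_load_roundtrip(self, std_world, std_splits, trained_model, tmp_path):
        _, _, test = std_splits
        path = str(tmp_path / "clf.json")
        save_model(trained_model, path)
        clone = load_model(path)
        a = predict_batch(trained_model, test[:30], std_world.docs, std_world.dag)
        b = predict_batch(clone, test[:30], std_world.docs, std_world.dag)
        assert [r.label for r in a] == [r.label for r in b]


def test_permutation_sanity(std_world, std_splits):
    """Shuffling training labels destroys test performance (leakage guard)."""
    import dataclasses

    from goaqc.evaluation import metrics_table

    train, dev, test = std_splits
    rng = np.random.default_rng(9)
    labels = [train[j].label for j in rng.permutation(len(train))]
    shuffled = [dataclasses.replace(i, label=l) for i, l in zip(train, labels)]
    model = train_classifier(shuffled, dev, std_world.dag, std_world.docs)
    preds = [r.label for r in predict_batch(model, test, std_world.docs, std_world.dag)]
    tab = metrics_table(preds, [i.label for i in test])
    macro = float(tab[tab["class"] == "macro"]["f1"].iloc[0])
    assert macro <= 0.3  # at or below the 4-way chance band


def test_signal_dial_monotone():
    """Test macro-F1 is non-decreasing in the generator's signal level."""
    from goaqc.evaluation import metrics_table

    scores = []
    for signal in (0.0, 0.5, 1.0):
        w = goaqc.generate_world(goaqc.WorldConfig(
            n_terms=100, n_levels=5, n_genes=30, n_documents=1500,
            signal=signal, seed=17))
        d = goaqc.build_dictionary(w.dag)
        cfg = goaqc.SynthesisConfig(train_size=2000, dev_size=0, test_consistent=119,
                                    test_per_type=24, seed=2)
        train, _, test = goaqc.assemble_datasets(w.annotations, w.dag, w.docs, d, cfg)
        model = train_classifier(train, [], w.dag, w.docs)
        preds = [r.label for r in predict_batch(model, test, w.docs, w.dag)]
        tab = metrics_table(preds, [i.label for i in test])
        scores.append(float(tab[tab["class"] == "macro"]["f1"].iloc[0]))
    assert scores[0] <= scores[1] <= scores[2]


def test_fusion_helps_when_depth_is_the_signal():
    """On a zero-signal world the classes differ mainly by term depth;
    fusing specificity embeddings then beats the plain encoder at equal
    seed and epochs."""
    from goaqc import specificity as sp
    from goaqc.evaluation import metrics_table

    w = goaqc.generate_world(goaqc.WorldConfig(
        n_terms=120, n_levels=5, n_genes=40, n_documents=1200,
        seed=13, signal=0.0))
    d = goaqc.build_dictionary(w.dag)
    cfg = goaqc.SynthesisConfig(train_size=1600, dev_size=80, test_consistent=100,
                                test_per_type=24, seed=2)
    train, dev, test = goaqc.assemble_datasets(w.annotations, w.dag, w.docs, d, cfg)
    feats = sp.init_node_features(w.dag, "structural", d=120)
    edges = sp.build_edge_dataset(w.dag, 0.74, np.random.default_rng(5))
    gnn = sp.train_edge_classifier(
        w.dag, feats, edges,
        sp.TrainingConfig(epochs=40, batch_size=64, warmup_steps=100, seed=0))
    emb = sp.extract_embeddings(gnn, w.dag)
    scores = {}
    for mode, e in (("plain", None), ("fusion", emb)):
        m = train_classifier(train, dev, w.dag, w.docs, embeddings=e,
                             cfg=TrainingConfig(epochs=5, learning_rate=5e-3, seed=0))
        preds = [r.label for r in predict_batch(m, test, w.docs, w.dag)]
        tab = metrics_table(preds, [i.label for i in test])
        scores[mode] = float(tab[tab["class"] == "macro"]["f1"].iloc[0])
    assert scores["fusion"] >= scores["plain"]
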