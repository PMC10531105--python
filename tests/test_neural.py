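"""Neural classifiers: tokenizer determinism, architecture contracts,
training-loop reductions, saliency extraction."""

import numpy as np
import pytest

import radresponse as rr
from radresponse.neural import weights_digest
from radresponse.tokenizer import build_tokenizer

from conftest import make_record


def separable_corpus(n_per_class=25, n_patients=20, prefix="P"):
    """Disjoint class vocabularies: a unigram rule suffices to classify."""
    words = {0: "aquamarine", 1: "byzantium", 2: "celadon", 3: "damson"}
    fillers = ["alpha", "bravo", "charlie", "delta", "echo", "foxtrot"]
    rng = np.random.default_rng(1)
    recs = []
    for code, w in words.items():
        for i in range(n_per_class):
            f1, f2 = rng.choice(fillers, size=2, replace=False)
            recs.append(rr.ReportRecord(
                report_id=f"{prefix}R{code}_{i}",
                patient_id=f"{prefix}{rng.integers(n_patients)}_{code}",
                conclusion_text=f"The {f1} marker shows {w} pattern. "
                                f"Also {f2} noted.",
                label=rr.ResponseLabel(code)))
    return rr.Corpus(recs)


@pytest.fixture(scope="module")
def separable_splits():
    train = separable_corpus(25, prefix="tr")
    dev = separable_corpus(8, prefix="dv")
    return train, dev


class TestTokenizer:
    def test_deterministic_vocabulary(self, small_corpus):
        a = build_tokenizer(small_corpus.texts(), vocab_cap=200)
        b = build_tokenizer(small_corpus.texts(), vocab_cap=200)
        assert a.itos == b.itos

    def test_vocab_cap_plus_two_specials(self, small_corpus):
        tok = build_tokenizer(small_corpus.texts(), vocab_cap=100)
        assert tok.vocab_size <= 102

    def test_unseen_token_maps_to_oov(self, small_corpus):
        tok = build_tokenizer(small_corpus.texts(), vocab_cap=500)
        ids = tok.encode("zyzzyva")
        assert ids == [tok.oov_id]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_tokenizer([])


class TestTraining:
    def test_transformer_learns_separable_fixture(self, separable_splits):
        train, dev = separable_splits
        model, hist = rr.train_supervised(
            rr.EncoderSpec(kind="tiny_transformer"), train, dev,
            rr.TrainConfig(epochs=10, learning_rate=1e-3), seed=0)
        assert hist.dev_accuracy.dropna().max() >= 0.95

    def test_training_loss_decreases_on_average(self, separable_splits):
        train, dev = separable_splits
        _, hist = rr.train_supervised(
            rr.EncoderSpec(kind="tiny_transformer"), train, dev,
            rr.TrainConfig(epochs=6), seed=1)
        per_epoch = hist.groupby("epoch").ce.mean()
        assert per_epoch.iloc[-1] < per_epoch.iloc[0]

    def test_same_seed_identical_weights(self, separable_splits):
        train, dev = separable_splits
        cfg = rr.TrainConfig(epochs=2)
        spec = rr.EncoderSpec(kind="cnn")
        a, _ = rr.train_supervised(spec, train, dev, cfg, seed=7)
        b, _ = rr.train_supervised(spec, train, dev, cfg, seed=7)
        assert weights_digest(a) == weights_digest(b)

    def test_shared_patients_rejected(self, separable_splits):
        train, _ = separable_splits
        with pytest.raises(ValueError, match="leakage"):
            rr.train_supervised(rr.EncoderSpec(), train, train,
                                rr.TrainConfig(epochs=1))

    @pytest.mark.parametrize("kind", ["bilstm", "cnn"])
    def test_alternative_architectures_train(self, kind, separable_splits):
        train, dev = separable_splits
        model, hist = rr.train_supervised(
            rr.EncoderSpec(kind=kind), train, dev,
            rr.TrainConfig(epochs=16), seed=0)
        assert hist.dev_accuracy.dropna().max() >= 0.9

    def test_bilstm_head_shape(self, separable_splits):
        train, dev = separable_splits
        model, _ = rr.train_supervised(
            rr.EncoderSpec(kind="bilstm"), train, dev,
            rr.TrainConfig(epochs=1), seed=0)
        assert model.head_hidden.W.shape[1] == 64
        assert model.head_out.W.shape == (64, 4)


class TestConsistencyTraining:
    def test_beta_zero_no_variant_ce_reduces_to_plain(self, separable_splits):
        train, dev = separable_splits
        cfg = rr.TrainConfig(epochs=2)
        spec = rr.EncoderSpec(kind="tiny_transformer")
        plain, hp = rr.train_supervised(spec, train, dev, cfg, seed=3)
        reduced, hr = rr.train_with_consistency(
            spec, train, dev,
            rr.AugmentationConfig(P=5, seed=0, include_variants_in_ce=False),
            rr.ConsistencyWeights(alpha=1.0, beta=0.0), cfg, seed=3)
        assert weights_digest(plain) == weights_digest(reduced)
        assert np.allclose(hp.ce.values, hr.ce.values)

    def test_loss_accounting_identity(self, separable_splits):
        train, dev = separable_splits
        _, hist = rr.train_with_consistency(
            rr.EncoderSpec(kind="tiny_transformer"), train, dev,
            rr.AugmentationConfig(P=3, seed=1),
            rr.ConsistencyWeights(alpha=1.0, beta=10.0),
            rr.TrainConfig(epochs=2), seed=0)
        assert np.allclose(hist.total, 1.0 * hist.ce + 10.0 * hist.mse)
        assert (hist.mse >= 0).all()


@pytest.fixture(scope="module")
def model(separable_splits):
    train, dev = separable_splits
    trained, _ = rr.train_supervised(
        rr.EncoderSpec(kind="tiny_transformer"), train, dev,
        rr.TrainConfig(epochs=3), seed=0)
    return trained


class TestPrediction:
    def test_distribution_valid(self, model):
        p = model.predict_proba("The alpha marker shows celadon pattern.")
        assert p.shape == (4,)
        assert (p >= 0).all() and p.sum() == pytest.approx(1.0)

    def test_empty_text_rejected(self, model):
        with pytest.raises(ValueError):
            model.predict_proba("   ")

    def test_truncation_noop_for_short_text(self, model):
        short = "Stable disease."
        ids, mask = model.encode_batch([short])
        assert ids.shape[1] <= model.spec.max_seq_len
        assert mask.sum() == len(model.tokenizer.encode(short))

    def test_saliency_weights_normalized(self, model):
        tokens, w = rr.saliency(model, "The alpha marker shows damson pattern.")
        assert len(tokens) == len(w)
        assert w.min() >= 0.0 and w.max() == pytest.approx(1.0)
        html = rr.render_saliency(tokens, w)
        assert html.count("<span") == len(tokens)

    def test_saliency_rejects_non_attention_model(self, separable_splits):
        train, dev = separable_splits
        cnn, _ = rr.train_supervised(rr.EncoderSpec(kind="cnn"), train, dev,
                                     rr.TrainConfig(epochs=1), seed=0)
        with pytest.raises(ValueError, match="gradient"):
            rr.saliency(cnn, "Stable disease.")
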