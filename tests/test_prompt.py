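"""Cloze-prompt machinery: prompt construction, verbalizer scoring, the two
fine-tuning losses, few-shot sampling."""

import numpy as np
import pytest

import radresponse as rr
from radresponse._autograd import Adam
from radresponse.prompt import TinyMaskedLM, default_label_span

from conftest import make_record


@pytest.fixture(scope="module")
def mlm(small_corpus):
    return TinyMaskedLM.build(small_corpus.texts()[:200], vocab_cap=500, seed=0)


@pytest.fixture(scope="module")
def spec():
    return rr.PromptSpec()


class TestPromptSpec:
    def test_default_template_and_verbalizer(self, spec):
        assert spec.template == "[INPUT_TEXT] [SEP] In summary, this is a [MASK]"
        assert spec.verbalizer[0] == "no evidence of disease"
        assert spec.verbalizer[3] == "progressive disease"

    def test_missing_placeholder_rejected(self):
        with pytest.raises(ValueError, match="MASK"):
            rr.PromptSpec(template="[INPUT_TEXT] [SEP] no mask here")

    def test_duplicate_phrases_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rr.PromptSpec(verbalizer={0: "same", 1: "same", 2: "x", 3: "y"})


class TestBuildPrompt:
    def test_mask_span_at_tail(self, mlm, spec):
        ids, mpos, span = rr.build_prompt("Stable disease.", spec,
                                          mlm.tokenizer, k=2)
        assert len(mpos) == 2
        assert mpos == [len(ids) - 2, len(ids) - 1]
        assert all(ids[p] == mlm.mask_id for p in mpos)

    def test_k1_single_mask(self, mlm, spec):
        ids, mpos, _ = rr.build_prompt("Stable disease.", spec,
                                       mlm.tokenizer, k=1)
        assert len(mpos) == 1

    def test_overlong_input_truncated_suffix_intact(self, mlm, spec):
        long_text = "Stable lesion. " * 200
        ids, mpos, span = rr.build_prompt(long_text, spec, mlm.tokenizer,
                                          k=2, max_len=64)
        assert len(ids) <= 64
        assert mpos[-1] == len(ids) - 1  # suffix (and mask span) survive
        assert span[1] - span[0] < len(mlm.tokenizer.encode(long_text))

    def test_affixes_alone_too_long_rejected(self, mlm, spec):
        with pytest.raises(ValueError, match="exceed"):
            rr.build_prompt("Stable.", spec, mlm.tokenizer, k=2, max_len=5)


class TestScoreLabels:
    def test_uniform_mlm_gives_uniform_distribution(self, spec, small_corpus):
        mlm = TinyMaskedLM.build(small_corpus.texts()[:200], vocab_cap=500,
                                 seed=0)
        # force uniform token distributions at every position
        mlm.lm_head.W.data[...] = 0.0
        mlm.lm_head.b.data[...] = 0.0
        for p in mlm.encoder.params():
            p.data[...] = 0.0
        ids, mpos, _ = rr.build_prompt("Stable disease.", spec, mlm.tokenizer,
                                       k=4)
        out = rr.score_labels(mlm, ids, mpos, spec, k=4)
        assert np.allclose(out, 0.25, atol=1e-9)

    def test_oracle_mass_on_stable_disease_tokens(self, mlm, spec):
        k = default_label_span(spec, mlm.tokenizer)
        ids, mpos, _ = rr.build_prompt("Liver lesion unchanged.", spec,
                                       mlm.tokenizer, k=k)
        logits = np.full((len(ids), mlm.tokenizer.vocab_size), -30.0)
        for j, tok in enumerate(mlm.tokenizer.encode("stable disease")):
            logits[mpos[j], tok] = 30.0

        class Oracle:
            tokenizer = mlm.tokenizer

            def token_log_probs(self, _ids):
                x = logits - logits.max(axis=-1, keepdims=True)
                return x - np.log(np.exp(x).sum(axis=-1, keepdims=True))

        out = rr.score_labels(Oracle(), ids, mpos, spec, k=k)
        assert int(np.argmax(out)) == int(rr.ResponseLabel.SD)

    def test_verbalizer_relabeling_equivariance(self, mlm, spec):
        k = default_label_span(spec, mlm.tokenizer)
        ids, mpos, _ = rr.build_prompt("Stable disease.", spec, mlm.tokenizer,
                                       k=k)
        base = rr.score_labels(mlm, ids, mpos, spec, k=k)
        perm = {0: spec.verbalizer[3], 1: spec.verbalizer[2],
                2: spec.verbalizer[1], 3: spec.verbalizer[0]}
        swapped = rr.score_labels(mlm, ids, mpos,
                                  rr.PromptSpec(verbalizer=perm), k=k)
        assert np.allclose(base, swapped[::-1])


class TestDecoupledLabelLoss:
    def test_uniform_mlm_closed_form(self):
        """Uniform 10-token model, single-token verbalizers, 4 candidates:
        loss = -[ln(0.1) + 3 ln(0.9)] / 4."""
        texts = ["alpha beta gamma delta epsilon zeta eta theta"]
        tok = rr.TinyMaskedLM.build(texts, vocab_cap=8, seed=0).tokenizer
        assert tok.vocab_size == 12  # 8 words + pad/oov + 2 specials

        # a tiny spec with single-token verbalizations
        pspec = rr.PromptSpec(verbalizer={0: "alpha", 1: "beta",
                                          2: "gamma", 3: "delta"})
        mlm = TinyMaskedLM(tok, seed=0)
        for p in mlm.params():
            p.data[...] = 0.0  # logits 0 -> uniform over the 12-token vocab
        ids, mpos, _ = rr.build_prompt("epsilon zeta.", pspec, tok, k=1)
        loss = rr.decoupled_label_loss(mlm, ids, mpos, pspec, true_label=0,
                                       k=1)
        p = 1.0 / 12
        expected = -(np.log(p) + 3 * np.log(1 - p)) / 4
        assert loss.data == pytest.approx(expected, rel=1e-6)

    def test_loss_decreases_after_gradient_step(self, small_corpus, spec):
        mlm = TinyMaskedLM.build(small_corpus.texts()[:100], vocab_cap=300,
                                 seed=1)
        k = default_label_span(spec, mlm.tokenizer)
        ids, mpos, _ = rr.build_prompt(small_corpus[0].conclusion_text, spec,
                                       mlm.tokenizer, k=k,
                                       max_len=mlm.max_seq_len)
        opt = Adam(mlm.params(), lr=1e-2)
        before = rr.decoupled_label_loss(mlm, ids, mpos, spec, 2, k)
        opt.zero_grad()
        before.backward()
        opt.step()
        after = rr.decoupled_label_loss(mlm, ids, mpos, spec, 2, k)
        assert after.data < before.data


class TestLabelConditionedMlmLoss:
    def test_zero_mask_ratio_error_path(self, mlm, spec):
        cfg = rr.PromptTrainConfig(mask_ratio=0.0)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="masked"):
            rr.label_conditioned_mlm_loss(mlm, "Stable disease in liver.",
                                          spec, 2, 2, cfg, rng)

    def test_true_candidate_oracle_low_false_high(self, small_corpus, spec):
        mlm = TinyMaskedLM.build(small_corpus.texts()[:100], vocab_cap=300,
                                 seed=2)
        cfg = rr.PromptTrainConfig(mask_ratio=0.5, seed=0)
        text = small_corpus[0].conclusion_text
        true = int(small_corpus[0].label)
        wrong = (true + 1) % 4
        lt = rr.label_conditioned_mlm_loss(mlm, text, spec, true, true, cfg,
                                           np.random.default_rng(1))
        lf = rr.label_conditioned_mlm_loss(mlm, text, spec, wrong, true, cfg,
                                           np.random.default_rng(1))
        # same masking (same rng seed): targets are inverted, so with a
        # near-uniform model both are ~ -ln(p) vs -ln(1-p) with p small
        assert lt.data > lf.data > 0.0

    def test_deterministic_given_rng_state(self, mlm, spec):
        cfg = rr.PromptTrainConfig(mask_ratio=0.3)
        a = rr.label_conditioned_mlm_loss(mlm, "Stable liver lesion again.",
                                          spec, 1, 2, cfg,
                                          np.random.default_rng(5))
        b = rr.label_conditioned_mlm_loss(mlm, "Stable liver lesion again.",
                                          spec, 1, 2, cfg,
                                          np.random.default_rng(5))
        assert a.data == b.data


class TestTrainPrompt:
    def test_zero_batches_returns_model_unchanged(self, mlm, spec,
                                                  small_corpus):
        split = rr.split_by_patient(small_corpus, rr.SplitSpec(seed=0))
        before = [p.data.copy() for p in mlm.params()]
        out, trace = rr.train_prompt(
            mlm, split.subset("train"), split.subset("dev"), spec,
            rr.PromptTrainConfig(num_batches=0))
        assert trace == []
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before, out.params()))

    def test_eval_trace_length(self, small_corpus, spec):
        mlm = TinyMaskedLM.build(small_corpus.texts()[:100], vocab_cap=200,
                                 seed=3)
        split = rr.split_by_patient(small_corpus, rr.SplitSpec(seed=0))
        dev = rr.Corpus(split.subset("dev").records[:10])
        train = rr.Corpus(split.subset("train").records[:20])
        _, trace = rr.train_prompt(
            mlm, train, dev, spec,
            rr.PromptTrainConfig(num_batches=10, eval_every=3,
                                 learning_rate=1e-4, batch_size=4))
        assert len(trace) == 10 // 3

    def test_shared_patients_rejected(self, mlm, spec, small_corpus):
        with pytest.raises(ValueError, match="share"):
            rr.train_prompt(mlm, small_corpus, small_corpus, spec,
                            rr.PromptTrainConfig(num_batches=1))


class TestFewShotSample:
    def test_identity_at_full_size(self, small_corpus):
        out = rr.few_shot_sample(small_corpus, len(small_corpus), seed=0)
        assert len(out) == len(small_corpus)

    def test_stratified_counts_at_100(self, small_corpus):
        out = rr.few_shot_sample(small_corpus, 100, seed=1)
        assert len(out) == 100
        got = np.bincount([int(r.label) for r in out], minlength=4)
        labels = np.array([int(l) for l in small_corpus.labels()])
        props = np.bincount(labels, minlength=4) / len(labels)
        expected = rr.corpus.largest_remainder(100, list(props))
        assert list(got) == expected

    def test_deterministic(self, small_corpus):
        a = rr.few_shot_sample(small_corpus, 50, seed=9)
        b = rr.few_shot_sample(small_corpus, 50, seed=9)
        assert [r.report_id for r in a] == [r.report_id for r in b]

    def test_oversized_request_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            rr.few_shot_sample(small_corpus, len(small_corpus) + 1)
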