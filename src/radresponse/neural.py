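"""Neural disease-response classifiers and their training loops.

Two trainers share one loop: plain supervised training (cross-entropy on
the original conclusions) and consistency-regularized training, where each
step additionally samples one sentence-permuted variant per training text
and penalizes the MSE between the label distributions of the original and
the variant (L = alpha * CE + beta * MSE).  With beta = 0 and variants kept
out of the CE term, the consistency trainer reduces exactly to the plain
one under the same seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._autograd import Adam, Tensor
from .augmentation import AugmentationConfig, ConsistencyWeights, permute_conclusion
from .corpus import Corpus, ResponseLabel
from .nn import BiLSTMEncoder, CNNEncoder, Linear, Module, TransformerEncoder
from .tokenizer import Tokenizer, build_tokenizer

__all__ = [
    "EncoderSpec",
    "TrainConfig",
    "NeuralClassifier",
    "train_supervised",
    "train_with_consistency",
    "weights_digest",
    "permutation_divergence",
]

ENCODER_KINDS = ("tiny_transformer", "bilstm", "cnn", "pretrained_adapter")


@dataclass(frozen=True)
class EncoderSpec:
    kind: str = "tiny_transformer"
    vocab_cap: int = 5000
    embedding_dim: int = 64
    hidden_size: int = 64
    n_layers: int = 2
    n_heads: int = 4
    ff_dim: int = 128
    max_seq_len: int = 64

    def __post_init__(self) -> None:
        if self.kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        for name in ("embedding_dim", "hidden_size", "n_layers", "n_heads",
                     "ff_dim", "max_seq_len", "vocab_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    learning_rate: float = 1e-3
    train_batch_size: int = 16
    eval_batch_size: int = 64
    max_seq_len: int = 64
    seeds: tuple[int, ...] = (0, 1, 2)
    patience: int | None = None  # epochs without dev improvement; None = off

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.train_batch_size < 1 or self.eval_batch_size < 1:
            raise ValueError("epochs and batch sizes must be positive")
        if len(self.seeds) < 1:
            raise ValueError("at least one seed required")


def _build_encoder(spec: EncoderSpec, vocab_size: int,
                   rng: np.random.Generator,
                   adapter: Callable[..., Module] | None = None) -> Module:
    if spec.kind == "tiny_transformer":
        return TransformerEncoder(
            vocab_size, dim=spec.embedding_dim, n_layers=spec.n_layers,
            n_heads=spec.n_heads, ff_dim=spec.ff_dim,
            max_seq_len=spec.max_seq_len, use_cls=True, rng=rng,
        )
    if spec.kind == "bilstm":
        return BiLSTMEncoder(vocab_size, embedding_dim=spec.embedding_dim,
                             hidden_size=spec.hidden_size, rng=rng)
    if spec.kind == "cnn":
        return CNNEncoder(vocab_size, embedding_dim=spec.embedding_dim,
                          n_filters=spec.hidden_size, rng=rng)
    if spec.kind == "pretrained_adapter":
        if adapter is None:
            raise ValueError("pretrained_adapter requires an adapter factory")
        return adapter(vocab_size=vocab_size, rng=rng)
    raise ValueError(spec.kind)


class NeuralClassifier(Module):
    """Tokenizer + encoder + dense(64) -> dense(4) softmax head."""

    def __init__(self, spec: EncoderSpec, tokenizer: Tokenizer,
                 rng: np.random.Generator,
                 adapter: Callable[..., Module] | None = None):
        self.spec = spec
        self.tokenizer = tokenizer
        self.encoder = _build_encoder(spec, tokenizer.vocab_size, rng, adapter)
        self.head_hidden = Linear(self.encoder.out_dim, 64, rng)
        self.head_out = Linear(64, 4, rng)

    # -- encoding ------------------------------------------------------------

    def encode_batch(self, texts: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        seqs = [self.tokenizer.encode(t, max_len=self.spec.max_seq_len)
                for t in texts]
        if any(len(s) == 0 for s in seqs):
            raise ValueError("cannot encode an empty text")
        T = max(len(s) for s in seqs)
        ids = np.zeros((len(seqs), T), dtype=np.intp)  # 0 = pad
        mask = np.zeros((len(seqs), T))
        for i, s in enumerate(seqs):
            ids[i, : len(s)] = s
            mask[i, : len(s)] = 1.0
        return ids, mask

    def logits(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        pooled = self.encoder(ids, mask)
        return self.head_out(self.head_hidden(pooled).relu())

    # -- inference -----------------------------------------------------------

    def predict_proba_batch(self, texts: Sequence[str],
                            batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(texts), batch_size):
            ids, mask = self.encode_batch(texts[i: i + batch_size])
            out.append(self.logits(ids, mask).softmax(axis=-1).data)
        return np.concatenate(out, axis=0)

    def predict_proba(self, text: str) -> np.ndarray:
        if not text or not text.strip():
            raise ValueError("predict_proba: empty text")
        return self.predict_proba_batch([text])[0]

    def predict(self, text: str) -> ResponseLabel:
        # np.argmax takes the first maximum, i.e. the lowest class code on ties
        return ResponseLabel(int(np.argmax(self.predict_proba(text))))

    def accuracy(self, corpus: Corpus, batch_size: int = 64) -> float:
        probs = self.predict_proba_batch(corpus.texts(), batch_size)
        pred = np.argmax(probs, axis=1)
        gold = np.asarray([int(l) for l in corpus.labels()])
        return float(np.mean(pred == gold))


def weights_digest(model: Module) -> str:
    """SHA-256 over all parameter arrays (reproducibility checks)."""
    h = hashlib.sha256()
    for p in model.params():
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def _check_disjoint(train: Corpus, dev: Corpus) -> None:
    overlap = set(train.patient_index) & set(dev.patient_index)
    if overlap:
        raise ValueError(
            f"train/dev corpora share patients (leakage): {sorted(overlap)[:5]}"
        )


def _ce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def train_with_consistency(
    spec: EncoderSpec,
    train: Corpus,
    dev: Corpus,
    aug: AugmentationConfig | None,
    weights: ConsistencyWeights | None,
    config: TrainConfig,
    seed: int = 0,
    adapter: Callable[..., Module] | None = None,
) -> tuple[NeuralClassifier, pd.DataFrame]:
    """Shared training loop; ``aug=None`` gives plain supervised training.

    History rows carry (step, epoch, ce, mse, total) for every optimization
    step and the dev accuracy at each epoch end; the returned model holds
    the best-dev-accuracy weights.
    """
    _check_disjoint(train, dev)
    if weights is None:
        weights = ConsistencyWeights()
    if aug is not None and weights.beta == 0 and not aug.include_variants_in_ce:
        aug = None  # exact reduction to the plain trainer
    rng = np.random.default_rng(seed)
    tok = build_tokenizer(train.texts(), vocab_cap=spec.vocab_cap)
    model = NeuralClassifier(spec, tok, rng, adapter)
    opt = Adam(model.params(), lr=config.learning_rate)

    variants: list[list[str]] = []
    if aug is not None:
        for i, rec in enumerate(train.records):
            per_record = replace(aug, seed=(aug.seed * 1_000_003 + i) % 2**31)
            variants.append([v.text for v in permute_conclusion(rec, per_record)])
        var_rng = np.random.default_rng((seed + 1) * 7_919)

    texts = train.texts()
    labels = np.asarray([int(l) for l in train.labels()])
    n = len(texts)
    history: list[dict] = []
    best_acc, best_state = -1.0, model.state()
    stall = 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.train_batch_size):
            idx = order[start: start + config.train_batch_size]
            batch_texts = [texts[i] for i in idx]
            batch_labels = labels[idx]
            if aug is None:
                ids, mask = model.encode_batch(batch_texts)
                logits = model.logits(ids, mask)
                ce = _ce_loss(logits, batch_labels)
                mse = Tensor(0.0)
            else:
                paired = [i for i in idx if variants[i]]
                var_texts = [
                    variants[i][int(var_rng.integers(len(variants[i])))]
                    for i in paired
                ]
                all_texts = batch_texts + var_texts
                ids, mask = model.encode_batch(all_texts)
                logits = model.logits(ids, mask)
                B = len(batch_texts)
                if aug.include_variants_in_ce:
                    var_labels = np.asarray(
                        [labels[i] for i in paired], dtype=np.intp)
                    ce = _ce_loss(logits, np.concatenate([batch_labels,
                                                          var_labels]))
                else:
                    ce = _ce_loss(logits[np.arange(B)], batch_labels)
                if paired:
                    probs = logits.softmax(axis=-1)
                    orig_rows = np.asarray(
                        [list(idx).index(i) for i in paired], dtype=np.intp)
                    p_orig = probs[orig_rows]
                    p_var = probs[np.arange(B, B + len(paired))]
                    mse = ((p_orig - p_var) ** 2).mean()
                else:
                    mse = Tensor(0.0)
            total = weights.alpha * ce + weights.beta * mse
            opt.zero_grad()
            total.backward()
            opt.step()
            step += 1
            history.append({
                "step": step, "epoch": epoch,
                "ce": float(ce.data), "mse": float(mse.data),
                "total": float(total.data), "dev_accuracy": np.nan,
            })
        acc = model.accuracy(dev, config.eval_batch_size)
        history[-1]["dev_accuracy"] = acc
        if acc > best_acc:
            best_acc, best_state = acc, model.state()
            stall = 0
        else:
            stall += 1
            if config.patience is not None and stall > config.patience:
                break
    model.load_state(best_state)
    return model, pd.DataFrame(history)


def train_supervised(
    spec: EncoderSpec,
    train: Corpus,
    dev: Corpus,
    config: TrainConfig,
    seed: int = 0,
    adapter: Callable[..., Module] | None = None,
) -> tuple[NeuralClassifier, pd.DataFrame]:
    """Plain cross-entropy training (no augmentation)."""
    return train_with_consistency(
        spec, train, dev, aug=None, weights=None,
        config=config, seed=seed, adapter=adapter,
    )


def permutation_divergence(
    model: NeuralClassifier, corpus: Corpus, P: int = 1, seed: int = 0
) -> float:
    """Mean MSE between label distributions of originals and permutations.

    Measures how order-sensitive a trained model still is on held-out data;
    consistency training is expected to drive this down.
    """
    from .augmentation import consistency_loss

    rng = np.random.default_rng(seed)
    divs = []
    for i, rec in enumerate(corpus):
        aug = AugmentationConfig(P=P, seed=int(rng.integers(2**31)))
        vars_ = permute_conclusion(rec, aug)
        if not vars_:
            continue
        p0 = model.predict_proba(rec.conclusion_text)
        for v in vars_:
            divs.append(consistency_loss(p0, model.predict_proba(v.text)))
    if not divs:
        raise ValueError("no multi-sentence records to measure divergence on")
    return float(np.mean(divs))
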