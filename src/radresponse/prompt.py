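"""Cloze-prompt few-shot fine-tuning over a pluggable masked language model.

The input is wrapped in a prompt — by default
``"[INPUT_TEXT] [SEP] In summary, this is a [MASK]"`` — and classification
is performed by scoring, at the mask span, the tokens of each class's
verbalization ({0: "no evidence of disease", 1: "partial response",
2: "stable disease", 3: "progressive disease"}).  Fine-tuning minimizes the
sum of a decoupled label loss (per-token binary cross-entropy over the
candidate verbalizations' tokens at the mask span) and a label-conditioned
masked-LM loss (masked-token reconstruction with targets inverted when the
inserted candidate label is wrong).

A tiny trainable transformer MLM serves as the default model; any object
with the same ``tokenizer`` / ``logits(ids, mask)`` surface (e.g. an adapter
around a large pretrained checkpoint) can be plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._autograd import Adam, Tensor
from .corpus import Corpus, ResponseLabel, largest_remainder
from .nn import Linear, Module, TransformerEncoder
from .tokenizer import Tokenizer, build_tokenizer

__all__ = [
    "PromptSpec",
    "PromptTrainConfig",
    "TinyMaskedLM",
    "build_prompt",
    "score_labels",
    "decoupled_label_loss",
    "label_conditioned_mlm_loss",
    "pretrain_mlm",
    "train_prompt",
    "train_head_only",
    "few_shot_sample",
]

DEFAULT_TEMPLATE = "[INPUT_TEXT] [SEP] In summary, this is a [MASK]"
DEFAULT_VERBALIZER = {
    0: "no evidence of disease",
    1: "partial response",
    2: "stable disease",
    3: "progressive disease",
}
_EPS = 1e-7


@dataclass(frozen=True)
class PromptSpec:
    template: str = DEFAULT_TEMPLATE
    verbalizer: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_VERBALIZER))

    def __post_init__(self) -> None:
        for ph in ("[INPUT_TEXT]", "[SEP]", "[MASK]"):
            if self.template.count(ph) != 1:
                raise ValueError(f"template must contain {ph} exactly once")
        if sorted(self.verbalizer) != [0, 1, 2, 3]:
            raise ValueError("verbalizer must cover class codes 0..3")
        phrases = list(self.verbalizer.values())
        if len(set(phrases)) != len(phrases):
            raise ValueError("verbalizer phrases must be pairwise distinct")


@dataclass(frozen=True)
class PromptTrainConfig:
    num_batches: int = 2000
    learning_rate: float = 1e-5
    eval_every: int = 100
    max_label_tokens: int | None = None  # None: longest verbalization
    mask_ratio: float = 0.15
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_batches < 0 or self.eval_every < 1 or self.batch_size < 1:
            raise ValueError("invalid prompt training sizes")
        if self.max_label_tokens is not None and self.max_label_tokens < 1:
            raise ValueError("max_label_tokens must be >= 1")
        if not (0.0 <= self.mask_ratio <= 1.0):
            raise ValueError("mask_ratio must be in [0,1]")


class TinyMaskedLM(Module):
    """Small trainable masked LM satisfying the masked-LM contract."""

    SPECIALS = ("[sep]", "[mask]")

    def __init__(self, tokenizer: Tokenizer, dim: int = 64, n_layers: int = 2,
                 n_heads: int = 4, ff_dim: int = 128, max_seq_len: int = 128,
                 input_budget: int | None = 56, seed: int = 0):
        for s in self.SPECIALS:
            if s not in tokenizer.stoi:
                raise ValueError(f"tokenizer lacks special token {s!r}")
        rng = np.random.default_rng(seed)
        self.tokenizer = tokenizer
        self.sep_id = tokenizer.special_id("[sep]")
        self.mask_id = tokenizer.special_id("[mask]")
        self.max_seq_len = max_seq_len
        # fixed input-segment budget: keeps the prompt suffix and mask span
        # at constant positions across inputs (padding is attention-masked)
        self.input_budget = input_budget
        self.encoder = TransformerEncoder(
            tokenizer.vocab_size, dim=dim, n_layers=n_layers, n_heads=n_heads,
            ff_dim=ff_dim, max_seq_len=max_seq_len, use_cls=False, rng=rng,
        )
        self.lm_head = Linear(dim, tokenizer.vocab_size, rng)

    @classmethod
    def build(cls, texts: Sequence[str], vocab_cap: int = 5000,
              seed: int = 0, **kwargs) -> "TinyMaskedLM":
        tok = build_tokenizer(texts, vocab_cap=vocab_cap,
                              extra_specials=list(cls.SPECIALS))
        return cls(tok, seed=seed, **kwargs)

    def logits(self, ids: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        ids = np.asarray(ids, dtype=np.intp)
        if ids.ndim == 1:
            ids = ids[None, :]
        if mask is None:
            mask = (ids != 0).astype(float)  # id 0 is reserved for padding
        return self.lm_head(self.encoder.hidden_states(ids, mask))

    def token_log_probs(self, ids: Sequence[int]) -> np.ndarray:
        """Per-position log distribution over the vocabulary (eval mode)."""
        out = self.logits(np.asarray(ids)).log_softmax(axis=-1)
        return out.data[0]

    def hidden(self, ids: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return self.encoder.hidden_states(ids, mask).data


def _verbalizer_tokens(spec: PromptSpec, tokenizer: Tokenizer,
                       k: int | None) -> dict[int, list[int]]:
    toks = {}
    for code, phrase in spec.verbalizer.items():
        ids = tokenizer.encode(phrase)
        if not ids:
            raise ValueError(f"verbalization {phrase!r} tokenizes to 0 tokens")
        toks[code] = ids if k is None else ids[:k]
    return toks


def default_label_span(spec: PromptSpec, tokenizer: Tokenizer) -> int:
    """Longest tokenized verbalization (the default mask-span length)."""
    return max(len(v) for v in _verbalizer_tokens(spec, tokenizer, None).values())


def build_prompt(
    text: str, spec: PromptSpec, tokenizer: Tokenizer, k: int,
    max_len: int | None = None, pad_input_to: int | None = None,
) -> tuple[list[int], list[int], tuple[int, int]]:
    """Tokenize the cloze prompt around the input text.

    Returns (ids, mask_positions, input_span) where ``mask_positions`` are
    the k indices of the mask span and ``input_span`` is the half-open id
    range holding the input text.  If the prompt exceeds ``max_len`` the
    input text is truncated from the tail; the prompt suffix never is.

    ``pad_input_to`` right-pads (or truncates) the input segment to a fixed
    token budget so the prompt suffix and mask span always occupy the same
    positions regardless of input length; padding is excluded from
    attention, so this changes only where the suffix sits, not what it can
    attend to.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sep_id = tokenizer.special_id("[sep]")
    mask_id = tokenizer.special_id("[mask]")
    before, after = spec.template.split("[INPUT_TEXT]")

    def render(chunk: str) -> list[int]:
        ids: list[int] = []
        for word in chunk.split():
            if word == "[SEP]":
                ids.append(sep_id)
            elif word == "[MASK]":
                ids.extend([mask_id] * k)
            else:
                ids.extend(tokenizer.encode(word))
        return ids

    prefix, suffix = render(before), render(after)
    input_ids = tokenizer.encode(text)
    if max_len is not None:
        budget = max_len - len(prefix) - len(suffix)
        if budget < 1:
            raise ValueError("prompt affixes alone exceed the maximum length")
        if pad_input_to is not None:
            budget = min(budget, pad_input_to)
        input_ids = input_ids[:budget]
    elif pad_input_to is not None:
        input_ids = input_ids[:pad_input_to]
    if pad_input_to is not None and len(input_ids) < pad_input_to:
        input_ids = input_ids + [tokenizer.pad_id] * (
            pad_input_to - len(input_ids))
    ids = prefix + input_ids + suffix
    mask_positions = [i for i, t in enumerate(ids) if t == mask_id]
    span = (len(prefix), len(prefix) + len(input_ids))
    return ids, mask_positions, span


def score_labels(
    mlm: TinyMaskedLM, ids: Sequence[int], mask_positions: Sequence[int],
    spec: PromptSpec, k: int | None = None,
) -> np.ndarray:
    """Class distribution from mean per-token verbalization log-probability.

    Each class is scored by the mean log-probability of its (length-
    normalized) verbalization tokens at the mask span; the four scores are
    softmax-normalized into a label distribution.
    """
    k = len(mask_positions) if k is None else k
    vtoks = _verbalizer_tokens(spec, mlm.tokenizer, k)
    logp = mlm.token_log_probs(ids)
    scores = np.empty(4)
    for code, toks in vtoks.items():
        positions = list(mask_positions)[: len(toks)]
        scores[code] = np.mean([logp[p, t] for p, t in zip(positions, toks)])
    e = np.exp(scores - scores.max())
    return e / e.sum()


def decoupled_label_loss(
    mlm: TinyMaskedLM, ids: Sequence[int], mask_positions: Sequence[int],
    spec: PromptSpec, true_label: "int | ResponseLabel", k: int | None = None,
    full_vocab_negatives: bool = False,
) -> Tensor:
    """Per-token BCE over candidate verbalizations at the mask span.

    True-label tokens are pushed toward probability 1, competing candidates'
    tokens toward 0; the loss is the mean over involved (position, token)
    pairs.  With ``full_vocab_negatives`` every non-true vocabulary token at
    each position acts as a negative instead.
    """
    true_label = int(true_label)
    k = len(mask_positions) if k is None else k
    vtoks = _verbalizer_tokens(spec, mlm.tokenizer, k)
    probs = mlm.logits(np.asarray(ids)).softmax(axis=-1)[0]
    terms: list[Tensor] = []
    if full_vocab_negatives:
        true_toks = vtoks[true_label]
        for j, pos in enumerate(list(mask_positions)[: len(true_toks)]):
            row = probs[pos].clip(_EPS, 1 - _EPS)
            target = np.zeros(mlm.tokenizer.vocab_size)
            target[true_toks[j]] = 1.0
            bce = -(Tensor(target) * row.log()
                    + Tensor(1 - target) * (1 - row).log())
            terms.append(bce.mean())
        return sum(terms[1:], terms[0]) * (1.0 / len(terms))
    for code, toks in vtoks.items():
        for j, pos in enumerate(list(mask_positions)[: len(toks)]):
            p = probs[pos, toks[j]].clip(_EPS, 1 - _EPS)
            terms.append(-(p.log()) if code == true_label
                         else -((1 - p).log()))
    return sum(terms[1:], terms[0]) * (1.0 / len(terms))


def label_conditioned_mlm_loss(
    mlm: TinyMaskedLM, text: str, spec: PromptSpec,
    candidate_label: "int | ResponseLabel", true_label: "int | ResponseLabel",
    config: PromptTrainConfig, rng: np.random.Generator,
) -> Tensor:
    """Masked-token reconstruction with label-dependent targets.

    The mask span is filled with the candidate's verbalization, input-text
    tokens are masked independently at ``mask_ratio``, and the model must
    reconstruct them (target probability 1) when the candidate is the true
    label, or not reconstruct them (target 0) otherwise.
    """
    candidate_label, true_label = int(candidate_label), int(true_label)
    kmax = config.max_label_tokens or default_label_span(spec, mlm.tokenizer)
    cand_toks = _verbalizer_tokens(spec, mlm.tokenizer, kmax)[candidate_label]
    ids, mask_positions, span = build_prompt(
        text, spec, mlm.tokenizer, k=len(cand_toks), max_len=mlm.max_seq_len,
        pad_input_to=mlm.input_budget)
    ids = list(ids)
    for pos, tok in zip(mask_positions, cand_toks):
        ids[pos] = tok
    input_positions = [p for p in range(span[0], span[1])
                       if ids[p] != mlm.tokenizer.pad_id]
    if not input_positions:
        raise ValueError("no input-text tokens available to mask")
    chosen = [p for p in input_positions if rng.random() < config.mask_ratio]
    if not chosen:  # resample once, then give up
        chosen = [p for p in input_positions if rng.random() < config.mask_ratio]
    if not chosen:
        raise ValueError(
            "no input tokens were masked (mask_ratio too low for this text)")
    originals = [ids[p] for p in chosen]
    masked = list(ids)
    for p in chosen:
        masked[p] = mlm.mask_id
    probs = mlm.logits(np.asarray(masked)).softmax(axis=-1)[0]
    p_orig = probs[np.asarray(chosen), np.asarray(originals)].clip(_EPS, 1 - _EPS)
    if candidate_label == true_label:
        return -(p_orig.log()).mean()
    return -((1 - p_orig).log()).mean()


def _pad_batch(seqs: list[list[int]]) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    ids = np.zeros((len(seqs), T), dtype=np.intp)
    mask = np.zeros((len(seqs), T))
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
    mask = (ids != 0).astype(float)
    return ids, mask


def _decoupled_label_loss_batch(
    mlm: TinyMaskedLM, seqs: list[list[int]], mpos: list[list[int]],
    spec: PromptSpec, labels: list[int], k: int,
) -> Tensor:
    """Batched decoupled label loss (mean over examples of per-pair means)."""
    vtoks = _verbalizer_tokens(spec, mlm.tokenizer, k)
    ids, mask = _pad_batch(seqs)
    probs = mlm.logits(ids, mask).softmax(axis=-1)
    rows, cols, toks, signs, weights = [], [], [], [], []
    for i, (positions, true) in enumerate(zip(mpos, labels)):
        pairs = [(p, t, c == true) for c, ts in vtoks.items()
                 for p, t in zip(positions[: len(ts)], ts)]
        for p, t, is_true in pairs:
            rows.append(i)
            cols.append(p)
            toks.append(t)
            signs.append(1.0 if is_true else 0.0)
            weights.append(1.0 / (len(pairs) * len(seqs)))
    p = probs[np.asarray(rows), np.asarray(cols),
              np.asarray(toks)].clip(_EPS, 1 - _EPS)
    s, w = np.asarray(signs), np.asarray(weights)
    bce = -(Tensor(s) * p.log() + Tensor(1 - s) * (1 - p).log())
    return (bce * Tensor(w)).sum()


def _label_conditioned_batch(
    mlm: TinyMaskedLM, records, spec: PromptSpec, candidates: list[int],
    config: "PromptTrainConfig", rng: np.random.Generator,
) -> Tensor | None:
    """Batched label-conditioned MLM loss; None if no example masked."""
    kmax = config.max_label_tokens or default_label_span(spec, mlm.tokenizer)
    vtoks = _verbalizer_tokens(spec, mlm.tokenizer, kmax)
    seqs, chosen_all, originals_all, signs = [], [], [], []
    for rec, cand in zip(records, candidates):
        cand_toks = vtoks[cand]
        ids, mpos, span = build_prompt(rec.conclusion_text, spec,
                                       mlm.tokenizer, k=len(cand_toks),
                                       max_len=mlm.max_seq_len,
                                       pad_input_to=mlm.input_budget)
        ids = list(ids)
        for pos, tok in zip(mpos, cand_toks):
            ids[pos] = tok
        input_positions = [p for p in range(span[0], span[1])
                           if ids[p] != mlm.tokenizer.pad_id]
        chosen = [p for p in input_positions
                  if rng.random() < config.mask_ratio]
        if not chosen:
            chosen = [p for p in input_positions
                      if rng.random() < config.mask_ratio]
        if not chosen:
            continue
        originals = [ids[p] for p in chosen]
        for p in chosen:
            ids[p] = mlm.mask_id
        seqs.append(ids)
        chosen_all.append(chosen)
        originals_all.append(originals)
        signs.append(1.0 if cand == int(rec.label) else 0.0)
    if not seqs:
        return None
    ids, mask = _pad_batch(seqs)
    probs = mlm.logits(ids, mask).softmax(axis=-1)
    rows, cols, toks, s, w = [], [], [], [], []
    for i, (chosen, originals) in enumerate(zip(chosen_all, originals_all)):
        for p, t in zip(chosen, originals):
            rows.append(i)
            cols.append(p)
            toks.append(t)
            s.append(signs[i])
            w.append(1.0 / (len(chosen) * len(seqs)))
    p = probs[np.asarray(rows), np.asarray(cols),
              np.asarray(toks)].clip(_EPS, 1 - _EPS)
    s, w = np.asarray(s), np.asarray(w)
    bce = -(Tensor(s) * p.log() + Tensor(1 - s) * (1 - p).log())
    return (bce * Tensor(w)).sum()


def _mlm_batch_ce(mlm: TinyMaskedLM, batch_ids: list[list[int]],
                  mask_ratio: float, rng: np.random.Generator) -> Tensor:
    """Standard masked-LM cross-entropy on a batch (for brief pretraining)."""
    T = max(len(s) for s in batch_ids)
    ids = np.zeros((len(batch_ids), T), dtype=np.intp)
    mask = np.zeros((len(batch_ids), T))
    targets, rows, cols = [], [], []
    for i, seq in enumerate(batch_ids):
        ids[i, : len(seq)] = seq
        mask[i, : len(seq)] = 1.0
        chosen = [j for j in range(len(seq)) if rng.random() < mask_ratio]
        if not chosen:
            chosen = [int(rng.integers(len(seq)))]
        for j in chosen:
            targets.append(seq[j])
            rows.append(i)
            cols.append(j)
            ids[i, j] = mlm.mask_id
    logp = mlm.logits(ids, mask).log_softmax(axis=-1)
    picked = logp[np.asarray(rows), np.asarray(cols), np.asarray(targets)]
    return -picked.mean()


def pretrain_mlm(
    mlm: TinyMaskedLM, texts: Sequence[str], n_batches: int = 300,
    batch_size: int = 16, mask_ratio: float = 0.15, lr: float = 1e-3,
    seed: int = 0,
) -> TinyMaskedLM:
    """Briefly pretrain the tiny MLM on unlabeled conclusion texts."""
    rng = np.random.default_rng(seed)
    encoded = [mlm.tokenizer.encode(t, max_len=mlm.max_seq_len) for t in texts]
    encoded = [e for e in encoded if e]
    opt = Adam(mlm.params(), lr=lr)
    for _ in range(n_batches):
        idx = rng.choice(len(encoded), size=min(batch_size, len(encoded)),
                         replace=False)
        loss = _mlm_batch_ce(mlm, [encoded[i] for i in idx], mask_ratio, rng)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return mlm


def _prompt_accuracy(mlm: TinyMaskedLM, corpus: Corpus, spec: PromptSpec,
                     k: int, batch_size: int = 64) -> float:
    vtoks = _verbalizer_tokens(spec, mlm.tokenizer, k)
    correct = 0
    for start in range(0, len(corpus), batch_size):
        chunk = corpus.records[start: start + batch_size]
        seqs, mpos = [], []
        for rec in chunk:
            ids, mp, _ = build_prompt(rec.conclusion_text, spec,
                                      mlm.tokenizer, k=k,
                                      max_len=mlm.max_seq_len,
                                      pad_input_to=mlm.input_budget)
            seqs.append(list(ids))
            mpos.append(list(mp))
        ids, mask = _pad_batch(seqs)
        logp = mlm.logits(ids, mask).log_softmax(axis=-1).data
        for i, rec in enumerate(chunk):
            scores = np.empty(4)
            for code, toks in vtoks.items():
                positions = mpos[i][: len(toks)]
                scores[code] = np.mean(
                    [logp[i, p, t] for p, t in zip(positions, toks)])
            correct += int(np.argmax(scores)) == int(rec.label)
    return correct / len(corpus)


def train_prompt(
    mlm: TinyMaskedLM, train: Corpus, dev: Corpus, spec: PromptSpec,
    config: PromptTrainConfig,
) -> tuple[TinyMaskedLM, list[tuple[int, float]]]:
    """ADAPET-style fine-tuning: decoupled label + label-conditioned MLM loss.

    Every step draws a batch from the few-shot corpus, computes the mean of
    the two losses (one candidate label sampled uniformly per example for
    the label-conditioned term), and takes an Adam step; dev accuracy is
    evaluated every ``eval_every`` batches and the best-dev state returned.
    """
    overlap = set(train.patient_index) & set(dev.patient_index)
    if overlap:
        raise ValueError(f"train/dev share patients: {sorted(overlap)[:5]}")
    if config.num_batches == 0:
        return mlm, []
    rng = np.random.default_rng(config.seed)
    k = config.max_label_tokens or default_label_span(spec, mlm.tokenizer)
    opt = Adam(mlm.params(), lr=config.learning_rate)
    n = len(train)
    trace: list[tuple[int, float]] = []
    best_acc, best_state = -1.0, mlm.state()
    for b in range(config.num_batches):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        records = [train[int(i)] for i in idx]
        seqs, mpos = [], []
        for rec in records:
            ids, mp, _ = build_prompt(rec.conclusion_text, spec,
                                      mlm.tokenizer, k=k,
                                      max_len=mlm.max_seq_len,
                                      pad_input_to=mlm.input_budget)
            seqs.append(list(ids))
            mpos.append(list(mp))
        loss = _decoupled_label_loss_batch(
            mlm, seqs, mpos, spec, [int(r.label) for r in records], k)
        candidates = [int(rng.integers(4)) for _ in records]
        mlm_term = _label_conditioned_batch(mlm, records, spec, candidates,
                                            config, rng)
        if mlm_term is not None:
            loss = loss + mlm_term
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (b + 1) % config.eval_every == 0:
            acc = _prompt_accuracy(mlm, dev, spec, k)
            trace.append((b + 1, acc))
            if acc > best_acc:
                best_acc, best_state = acc, mlm.state()
    if trace:
        mlm.load_state(best_state)
    return mlm, trace


def train_head_only(
    mlm: TinyMaskedLM, train: Corpus, dev: Corpus | None = None,
    config: PromptTrainConfig | None = None, seed: int = 0,
):
    """Head-only fine-tuning baseline on the same frozen encoder.

    Mean-pooled hidden states of the (frozen) masked LM feed the package's
    standard dense(64) -> dense(4) classification head, trained with the
    same optimizer, batch budget and best-dev selection as the prompt arm.
    Returns a predict function mapping texts to ResponseLabels.
    """
    from .nn import Linear

    config = config or PromptTrainConfig()
    rng = np.random.default_rng(seed)

    def featurize(texts: Sequence[str]) -> np.ndarray:
        feats = []
        for t in texts:
            ids = mlm.tokenizer.encode(t, max_len=mlm.max_seq_len)
            h = mlm.hidden(np.asarray(ids)[None, :], np.ones((1, len(ids))))
            feats.append(h[0].mean(axis=0))
        return np.asarray(feats)

    X = featurize(train.texts())
    y = np.asarray([int(l) for l in train.labels()], dtype=np.intp)
    h1 = Linear(X.shape[1], 64, rng)
    h2 = Linear(64, 4, rng)
    params = h1.params() + h2.params()
    opt = Adam(params, lr=max(config.learning_rate, 1e-3))

    def forward(feats: np.ndarray) -> Tensor:
        return h2(h1(Tensor(feats)).relu())

    X_dev = featurize(dev.texts()) if dev is not None else None
    y_dev = (np.asarray([int(l) for l in dev.labels()])
             if dev is not None else None)
    best_acc, best_state = -1.0, [p.data.copy() for p in params]
    n = len(X)
    for b in range(max(config.num_batches, 1)):
        idx = rng.choice(n, size=min(config.batch_size, n), replace=False)
        logp = forward(X[idx]).log_softmax(axis=-1)
        loss = -(logp[np.arange(len(idx)), y[idx]]).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        if X_dev is not None and (b + 1) % config.eval_every == 0:
            acc = float(np.mean(
                np.argmax(forward(X_dev).data, axis=1) == y_dev))
            if acc > best_acc:
                best_acc = acc
                best_state = [p.data.copy() for p in params]
    if X_dev is not None:
        for p, s in zip(params, best_state):
            p.data[...] = s

    def predict(texts: Sequence[str]) -> list[ResponseLabel]:
        scores = forward(featurize(texts)).data
        return [ResponseLabel(int(c)) for c in np.argmax(scores, axis=1)]

    return predict


def few_shot_sample(corpus: Corpus, n_reports: int, seed: int = 0) -> Corpus:
    """Class-stratified subsample of exactly ``n_reports`` records.

    Per-class counts follow largest-remainder apportionment of the corpus's
    empirical class proportions; records are drawn without replacement with
    a seeded generator and returned in corpus order.
    """
    if n_reports > len(corpus):
        raise ValueError(f"n_reports={n_reports} exceeds corpus size {len(corpus)}")
    if n_reports == len(corpus):
        return Corpus(corpus.records)
    by_class: dict[int, list[int]] = {c: [] for c in range(4)}
    for i, rec in enumerate(corpus):
        by_class[int(rec.label)].append(i)
    props = [len(by_class[c]) / len(corpus) for c in range(4)]
    counts = largest_remainder(n_reports, props)
    # cap at availability; push any shortfall onto the most available classes
    shortfall = 0
    for c in range(4):
        if counts[c] > len(by_class[c]):
            shortfall += counts[c] - len(by_class[c])
            counts[c] = len(by_class[c])
    while shortfall > 0:
        room = sorted(range(4), key=lambda c: counts[c] - len(by_class[c]))
        for c in room:
            if counts[c] < len(by_class[c]):
                counts[c] += 1
                shortfall -= 1
                break
        else:
            raise ValueError("cannot satisfy n_reports")
        if shortfall == 0:
            break
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for c in range(4):
        if counts[c]:
            pick = rng.choice(len(by_class[c]), size=counts[c], replace=False)
            chosen.extend(by_class[c][j] for j in pick)
    chosen.sort()
    return Corpus(corpus.records[i] for i in chosen)
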