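"""Metrics, multi-seed aggregation, significance tests, learning curves,
agreement statistics, and token-saliency rendering.

For single-label multiclass classification, accuracy coincides with
micro-F1, micro-precision and micro-recall; the EvalResult invariants
encode that identity and the tests exercise it on randomized inputs.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
)

from .corpus import Corpus, ResponseLabel
from .prompt import few_shot_sample

__all__ = [
    "EvalResult",
    "RunSet",
    "AgreementStats",
    "PairedTResult",
    "evaluate",
    "aggregate_runs",
    "paired_t_test",
    "learning_curve",
    "cohen_kappa",
    "spearman_rho",
    "saliency",
    "render_saliency",
]

_LABELS = [0, 1, 2, 3]


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_f1: float
    per_class: pd.DataFrame  # rows NED..PD: precision, recall, f1, support
    confusion: np.ndarray    # 4x4, row = gold, column = predicted
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "micro": {"precision": self.micro_precision,
                      "recall": self.micro_recall, "f1": self.micro_f1},
            "macro": {"f1": self.macro_f1},
            "per_class": self.per_class.reset_index()
                             .rename(columns={"index": "label"})
                             .to_dict(orient="records"),
            "confusion_matrix": self.confusion.tolist(),
            "n": self.n,
        }


@dataclass(frozen=True)
class RunSet:
    results: tuple[EvalResult, ...]
    mean_accuracy: float
    sd_accuracy: float


@dataclass(frozen=True)
class AgreementStats:
    kappa: float
    spearman_rho: float


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    degenerate: bool


def _codes(labels: Sequence) -> np.ndarray:
    return np.asarray([int(l) for l in labels])


def evaluate(predictions: Sequence, gold: Sequence) -> EvalResult:
    """Full multiclass evaluation of predicted vs gold response labels."""
    pred, y = _codes(predictions), _codes(gold)
    if len(pred) != len(y):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(y)} gold")
    if len(y) == 0:
        raise ValueError("evaluate: empty inputs")
    cm = _sk_confusion(y, pred, labels=_LABELS)
    acc = float(np.trace(cm) / cm.sum())
    mi_p, mi_r, mi_f, _ = precision_recall_fscore_support(
        y, pred, labels=_LABELS, average="micro", zero_division=0)
    _, _, ma_f, _ = precision_recall_fscore_support(
        y, pred, labels=_LABELS, average="macro", zero_division=0)
    p, r, f, s = precision_recall_fscore_support(
        y, pred, labels=_LABELS, average=None, zero_division=0)
    per_class = pd.DataFrame(
        {"precision": p, "recall": r, "f1": f, "support": s},
        index=[l.name for l in ResponseLabel],
    )
    return EvalResult(
        accuracy=acc, micro_precision=float(mi_p), micro_recall=float(mi_r),
        micro_f1=float(mi_f), macro_f1=float(ma_f), per_class=per_class,
        confusion=cm, n=len(y),
    )


def aggregate_runs(results: Sequence[EvalResult]) -> RunSet:
    """Mean and sample standard deviation of accuracy over seeded runs."""
    if len(results) == 0:
        raise ValueError("aggregate_runs: empty result list")
    accs = np.asarray([r.accuracy for r in results])
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return RunSet(tuple(results), float(accs.mean()), sd)


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Classical paired t-test on per-unit (e.g. per-seed) accuracies.

    Zero variance of the differences is a degenerate case: identical inputs
    return (t=0, p=1); a constant non-zero difference returns an infinite t
    with undefined p, both flagged.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t_test needs two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTResult(t=0.0, p=1.0, degenerate=True)
        return PairedTResult(t=float(np.sign(d.mean()) * np.inf),
                             p=float("nan"), degenerate=True)
    t, p = sstats.ttest_rel(a, b)
    return PairedTResult(t=float(t), p=float(p), degenerate=False)


def learning_curve(
    trainer: Callable[[Corpus, int], Callable[[Sequence[str]], Sequence]],
    train: Corpus,
    test: Corpus,
    sizes: Sequence[int],
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Accuracy as a function of labeled training-set size.

    ``trainer(sub_corpus, seed)`` must return a predict function mapping a
    list of texts to labels.  For each size a stratified few-shot sample is
    drawn, a model trained, and accuracy measured on the fixed test corpus;
    rows report the mean and sd over seeds.
    """
    sizes = list(sizes)
    if any(s > len(train) for s in sizes):
        raise ValueError("a requested size exceeds the training corpus")
    if sorted(sizes) != sizes:
        raise ValueError("sizes must be ascending")
    gold = test.labels()
    rows = []
    for size in sizes:
        accs = []
        for seed in seeds:
            sub = few_shot_sample(train, size, seed=seed)
            predict = trainer(sub, seed)
            pred = predict(test.texts())
            accs.append(evaluate(pred, gold).accuracy)
        accs = np.asarray(accs)
        rows.append({"size": size, "mean_accuracy": float(accs.mean()),
                     "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1
                     else 0.0})
    return pd.DataFrame(rows)


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Chance-corrected inter-annotator agreement between two label lists."""
    a, b = _codes(rater_a), _codes(rater_b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("cohen_kappa needs two equal-length lists, n >= 2")
    if np.array_equal(a, b):
        return 1.0  # p_e = 1 with perfect agreement is not a failure mode
    return float(cohen_kappa_score(a, b, labels=_LABELS))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank ties."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_rho needs equal-length vectors, n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("spearman_rho undefined for a constant vector")
    return float(sstats.spearmanr(x, y).statistic)


def saliency(model, text: str) -> tuple[list[str], np.ndarray]:
    """Per-token attention saliency from a transformer classifier.

    Uses the mean over heads of the final layer's attention from the
    classification token to each input token, min-max normalized to [0,1].
    """
    encoder = getattr(model, "encoder", model)
    if not hasattr(encoder, "last_attention") or not getattr(
            encoder, "use_cls", False):
        raise ValueError(
            "saliency requires an attention-based classifier with a "
            "classification token; use a gradient-based method for other "
            "architectures")
    ids, mask = model.encode_batch([text])
    model.logits(ids, mask)
    attn = encoder.last_attention  # (1, heads, T+1, T+1)
    n_real = int(mask[0].sum())
    w = attn[0, :, 0, 1: 1 + n_real].mean(axis=0)
    lo, hi = w.min(), w.max()
    w = np.ones_like(w) if hi - lo < 1e-12 else (w - lo) / (hi - lo)
    tokens = model.tokenizer.decode(ids[0, :n_real])
    return tokens, w


def render_saliency(tokens: Sequence[str], weights: np.ndarray) -> str:
    """Shade each token with red intensity proportional to its weight."""
    if len(tokens) != len(weights):
        raise ValueError("token/weight length mismatch")
    spans = [
        f'<span style="background-color: rgba(255,0,0,{float(w):.3f})">'
        f"{_html.escape(tok)}</span>"
        for tok, w in zip(tokens, weights)
    ]
    return "<div>" + " ".join(spans) + "</div>"
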