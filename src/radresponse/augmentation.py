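"""Sentence-permutation data augmentation and the consistency objective.

Conclusion sentences in radiology reports are close to order-exchangeable,
so permuting them yields new, label-preserving training texts.  During
training, the divergence between the model's predicted label distribution on
an original text (y) and on a permuted variant (y_P) is penalized with a
mean-squared-error consistency term; the overall objective is

    L = alpha * L_CE + beta * L_MSE,   L_MSE = (1/C) * sum_c (y_c - y_P,c)^2

with C = 4 classes and defaults alpha = 1, beta = 10, P = 10 permuted
variants per training text.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import numpy as np

from .corpus import N_CLASSES, ReportRecord, normalize_text

__all__ = [
    "AugmentationConfig",
    "ConsistencyWeights",
    "PermutedVariant",
    "LossBreakdown",
    "split_sentences",
    "permute_conclusion",
    "consistency_loss",
    "total_loss",
]

# Trailing-dot words that never end a sentence.
ABBREVIATIONS = frozenset(
    {
        "e.g.", "i.e.", "cf.", "approx.", "vs.", "no.", "dr.", "fig.",
        "etc.", "ca.", "resp.", "est.",
    }
)

_NUMBERED_MARKER = re.compile(r"^\(?\d+[.)]$")
_SENT_END = re.compile(r"[.!?]+[\"')\]]?$")


@dataclass(frozen=True)
class AugmentationConfig:
    P: int = 10
    seed: int = 0
    max_attempts: int | None = None  # defaults to 100 * P
    include_variants_in_ce: bool = True

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError(f"P must be >= 1, got {self.P}")

    @property
    def attempts(self) -> int:
        return self.max_attempts if self.max_attempts is not None else 100 * self.P


@dataclass(frozen=True)
class ConsistencyWeights:
    alpha: float = 1.0
    beta: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("weights must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


@dataclass(frozen=True)
class PermutedVariant:
    parent_report_id: str
    order: tuple[int, ...]
    text: str


@dataclass(frozen=True)
class LossBreakdown:
    ce: float
    mse: float
    total: float


def split_sentences(text: str) -> list[str]:
    """Split a conclusion into sentences on terminal punctuation.

    Abbreviations ("e.g.", "approx.", ...), numbered-list markers ("1.",
    "(2)") and single-letter initials do not end a sentence.  Joining the
    output with single spaces reproduces the whitespace-normalized input.
    """
    norm = normalize_text(text)
    if not norm:
        raise ValueError("split_sentences: empty text")
    words = norm.split(" ")
    sentences: list[str] = []
    current: list[str] = []
    for word in words:
        current.append(word)
        low = word.lower()
        if not _SENT_END.search(word):
            continue
        if low in ABBREVIATIONS or _NUMBERED_MARKER.match(low):
            continue
        if len(low) == 2 and low[0].isalpha() and low.endswith("."):
            continue  # single-letter initial such as "J."
        sentences.append(" ".join(current))
        current = []
    if current:
        sentences.append(" ".join(current))
    return sentences


def permute_conclusion(
    record: ReportRecord, config: AugmentationConfig
) -> list[PermutedVariant]:
    """Produce up to P distinct non-identity sentence-order variants.

    For an n-sentence conclusion exactly min(P, n! - 1) variants are
    returned (0 for a single sentence).  Distinctness is enforced on the
    order vectors; if the text contains duplicate sentences, variants whose
    joined text coincides are additionally deduplicated.  Deterministic
    given the config seed.
    """
    sentences = split_sentences(record.conclusion_text)
    n = len(sentences)
    if n <= 1:
        return []
    rng = np.random.default_rng(config.seed)
    identity = tuple(range(n))
    n_available = math.factorial(n) - 1 if n <= 12 else None  # else effectively inf
    target = config.P if n_available is None else min(config.P, n_available)

    orders: list[tuple[int, ...]] = []
    if n_available is not None and n_available <= max(4 * config.P, 64):
        # small n: enumerate all non-identity orders and sample without replacement
        all_orders = [o for o in itertools.permutations(range(n)) if o != identity]
        idx = rng.choice(len(all_orders), size=target, replace=False)
        orders = [all_orders[i] for i in sorted(idx)]
    else:
        seen = {identity}
        attempts = 0
        while len(orders) < target and attempts < config.attempts:
            attempts += 1
            o = tuple(int(i) for i in rng.permutation(n))
            if o in seen:
                continue
            seen.add(o)
            orders.append(o)

    variants: list[PermutedVariant] = []
    seen_texts = {" ".join(sentences)}
    for order in orders:
        text = " ".join(sentences[i] for i in order)
        if text in seen_texts:
            continue  # duplicate sentences can make distinct orders collide
        seen_texts.add(text)
        variants.append(
            PermutedVariant(parent_report_id=record.report_id, order=order, text=text)
        )
    return variants


def _check_distribution(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (N_CLASSES,):
        raise ValueError(f"{name} must have length {N_CLASSES}, got shape {p.shape}")
    if np.any(p < -1e-9):
        raise ValueError(f"{name} has negative components")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1 (got {p.sum()!r})")
    return p


def consistency_loss(y, y_p) -> float:
    """Mean over the C=4 classes of the squared component differences.

    Symmetric, zero iff the two distributions coincide, and bounded above
    by 0.5 on the probability simplex (attained at orthogonal one-hots).
    """
    y = _check_distribution(y, "y")
    y_p = _check_distribution(y_p, "y_p")
    return float(np.mean((y - y_p) ** 2))


def total_loss(ce: float, mse: float, w: ConsistencyWeights) -> LossBreakdown:
    """Weighted objective L = alpha * CE + beta * MSE."""
    if ce < 0 or mse < 0:
        raise ValueError("loss components must be non-negative")
    return LossBreakdown(ce=ce, mse=mse, total=w.alpha * ce + w.beta * mse)
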