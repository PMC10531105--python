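"""Whitespace+punctuation tokenizer with a frequency-capped vocabulary.

Ids 0 and 1 are reserved for padding and out-of-vocabulary tokens; optional
extra special tokens (e.g. "[sep]", "[mask]" for the cloze-prompt models)
are appended after the regular vocabulary.  Vocabulary order is
deterministic: frequency descending, then lexicographic.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Sequence

__all__ = ["Tokenizer", "build_tokenizer", "PAD", "OOV"]

PAD = "<pad>"
OOV = "<oov>"

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:\.[0-9]+)?|[^\sa-z0-9]")


def word_tokenize(text: str, lowercase: bool = True) -> list[str]:
    if lowercase:
        text = text.lower()
    return _TOKEN_RE.findall(text)


class Tokenizer:
    def __init__(self, vocab: Sequence[str], extra_specials: Sequence[str] = ()):
        self.itos: list[str] = [PAD, OOV] + list(vocab) + list(extra_specials)
        if len(set(self.itos)) != len(self.itos):
            raise ValueError("duplicate tokens in vocabulary/specials")
        self.stoi = {tok: i for i, tok in enumerate(self.itos)}
        self.pad_id = 0
        self.oov_id = 1
        self.special_ids = {self.stoi[s] for s in extra_specials} | {0, 1}

    @property
    def vocab_size(self) -> int:
        return len(self.itos)

    def special_id(self, token: str) -> int:
        return self.stoi[token]

    def encode(self, text: str, max_len: int | None = None) -> list[int]:
        ids = [self.stoi.get(t, self.oov_id) for t in word_tokenize(text)]
        if max_len is not None:
            ids = ids[:max_len]  # truncate tail
        return ids

    def decode(self, ids: Iterable[int]) -> list[str]:
        return [self.itos[i] for i in ids]


def build_tokenizer(
    texts: Iterable[str],
    vocab_cap: int = 5000,
    extra_specials: Sequence[str] = (),
) -> Tokenizer:
    """Build a tokenizer from training texts.

    The vocabulary keeps at most ``vocab_cap`` tokens (by frequency, ties
    broken lexicographically); with no extras the total size is at most
    vocab_cap + 2 (cap plus the padding and OOV specials).
    """
    counts: Counter[str] = Counter()
    n_texts = 0
    for text in texts:
        n_texts += 1
        counts.update(word_tokenize(text))
    if n_texts == 0 or not counts:
        raise ValueError("build_tokenizer: empty corpus")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    vocab = [tok for tok, _ in ordered[:vocab_cap]]
    return Tokenizer(vocab, extra_specials=extra_specials)
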