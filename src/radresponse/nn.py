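"""Sequence-encoder building blocks on top of the autodiff engine.

Three small architectures are provided: a transformer encoder (pre-LN,
learned positional embeddings, optional classification token), a
bidirectional LSTM, and a 1-D convolutional encoder with masked max-pooling
over time.  All operate on right-padded integer id matrices with a 0/1
validity mask and are deliberately small enough to train on a CPU.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat, stack

__all__ = [
    "Linear",
    "Embedding",
    "LayerNorm",
    "TransformerEncoder",
    "BiLSTMEncoder",
    "CNNEncoder",
]

NEG_INF = -1e9


class Module:
    def params(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p.data[...] = s


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, n_in**-0.5, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.02, (n_vocab, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.W[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None  # (B, heads, T, T)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, D = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (hd**-0.5)
        bias = (1.0 - mask)[:, None, None, :] * NEG_INF  # mask padded keys
        attn = (scores + bias).softmax(axis=-1)
        self.last_attention = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.wo(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = x + self.attn(self.ln1(x), mask)
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class TransformerEncoder(Module):
    """Pre-LN transformer encoder with learned positional embeddings.

    With ``use_cls=True`` a learned classification token is prepended and
    its final hidden state is the pooled representation; attention weights
    of the last layer are kept for saliency extraction.
    """

    def __init__(self, vocab_size: int, dim: int = 64, n_layers: int = 2,
                 n_heads: int = 4, ff_dim: int = 128, max_seq_len: int = 128,
                 use_cls: bool = True, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.use_cls = use_cls
        self.max_seq_len = max_seq_len
        self.tok = Embedding(vocab_size, dim, rng)
        self.pos = Embedding(max_seq_len + (1 if use_cls else 0), dim, rng)
        self.cls = Tensor(rng.normal(0.0, 0.02, (dim,)), requires_grad=True) \
            if use_cls else None
        self.blocks = [TransformerBlock(dim, n_heads, ff_dim, rng)
                       for _ in range(n_layers)]
        self.ln_out = LayerNorm(dim)
        self.out_dim = dim

    def hidden_states(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        """(B, T[+1], dim) hidden states; position 0 is CLS when enabled."""
        B, T = ids.shape
        h = self.tok(ids)
        if self.use_cls:
            cls = self.cls.reshape(1, 1, -1) * np.ones((B, 1, 1))
            h = concat([cls, h], axis=1)
            mask = np.concatenate([np.ones((B, 1)), mask], axis=1)
            T = T + 1
        h = h + self.pos(np.arange(T))  # broadcasts over the batch
        for block in self.blocks:
            h = block(h, mask)
        return self.ln_out(h)

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        h = self.hidden_states(ids, mask)
        if self.use_cls:
            return h[:, 0, :]
        # masked mean pooling
        m = mask[:, :, None]
        return (h * m).sum(axis=1) / m.sum(axis=1)

    @property
    def last_attention(self) -> np.ndarray | None:
        return self.blocks[-1].attn.last_attention


class BiLSTMEncoder(Module):
    """Bidirectional LSTM; pooled output concatenates the two final states.

    Right-padding is handled by carrying the previous state through padded
    steps, so padding tokens never contribute to the pooled representation.
    """

    def __init__(self, vocab_size: int, embedding_dim: int = 64,
                 hidden_size: int = 64, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.hidden_size = hidden_size
        self.emb = Embedding(vocab_size, embedding_dim, rng)
        self.cells = [
            _LSTMCell(embedding_dim, hidden_size, rng),  # forward
            _LSTMCell(embedding_dim, hidden_size, rng),  # backward
        ]
        self.out_dim = 2 * hidden_size

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        x = self.emb(ids)  # (B, T, E)
        B, T = ids.shape
        finals = []
        for cell, order in zip(self.cells, (range(T), range(T - 1, -1, -1))):
            h = Tensor(np.zeros((B, self.hidden_size)))
            c = Tensor(np.zeros((B, self.hidden_size)))
            for t in order:
                m = mask[:, t][:, None]
                h_new, c_new = cell(x[:, t, :], h, c)
                h = h_new * m + h * (1.0 - m)
                c = c_new * m + c * (1.0 - m)
            finals.append(h)
        return concat(finals, axis=-1)


class _LSTMCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.wx = Linear(n_in, 4 * n_hidden, rng)
        self.wh = Linear(n_hidden, 4 * n_hidden, rng)

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        z = self.wx(x) + self.wh(h)
        n = self.n_hidden
        i = z[:, 0 * n: 1 * n].sigmoid()
        f = z[:, 1 * n: 2 * n].sigmoid()
        g = z[:, 2 * n: 3 * n].tanh()
        o = z[:, 3 * n: 4 * n].sigmoid()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new


class CNNEncoder(Module):
    """Embedding -> 1-D convolution -> masked max-pooling over time."""

    def __init__(self, vocab_size: int, embedding_dim: int = 64,
                 n_filters: int = 64, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kernel_size = kernel_size
        self.emb = Embedding(vocab_size, embedding_dim, rng)
        self.W = Tensor(
            rng.normal(0.0, (kernel_size * embedding_dim) ** -0.5,
                       (kernel_size, embedding_dim, n_filters)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)
        self.out_dim = n_filters

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        x = self.emb(ids)  # (B, T, E)
        B, T = ids.shape
        k = self.kernel_size
        pad = k // 2
        zeros = Tensor(np.zeros((B, pad, x.shape[-1])))
        xp = concat([zeros, x, zeros], axis=1)
        conv = None
        for j in range(k):
            term = xp[:, j: j + T, :] @ self.W[j]
            conv = term if conv is None else conv + term
        conv = (conv + self.b).relu()
        neg = (1.0 - mask)[:, :, None] * NEG_INF  # exclude padding from pooling
        return (conv + neg).max(axis=1)
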