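"""Transformer building blocks on the :mod:`gazetwin.autodiff` engine.

Pre-norm multi-head attention encoder/decoder layers, sinusoidal positional
encodings (1-D for text, separable 2-D for the image patch grid), and small
MLP heads.  Parameters are float64; initialization is Xavier-uniform drawn
from a caller-supplied ``numpy`` generator so model construction is fully
seeded.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, embedding, softmax

NEG_INF = -1e9  # additive attention mask value for padded keys


class Module:
    """Tiny parameter container with named-parameter recursion."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(_xavier(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self._eps) ** -0.5) * self.gamma + self.beta


class Embedding(Module):
    def __init__(self, n_vocab: int, d: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 1.0 / math.sqrt(d), size=(n_vocab, d)),
                        requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.W, ids)


class MultiheadAttention(Module):
    """Standard scaled dot-product attention with ``n_heads`` heads.

    ``key_padding_mask`` (B, S_k) has 1 for usable keys and 0 for padded keys;
    padded keys receive an additive ``NEG_INF`` logit so their attention
    weight is exactly 0 after softmax (up to float underflow).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)
        self._h = n_heads
        self._dk = d_model // n_heads

    def _split(self, x: Tensor, B: int, S: int) -> Tensor:
        return x.reshape(B, S, self._h, self._dk).transpose(0, 2, 1, 3)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor,
                 key_padding_mask: np.ndarray | None = None) -> Tensor:
        B, Sq, d = query.shape
        Sk = key.shape[1]
        q = self._split(self.q(query), B, Sq)
        k = self._split(self.k(key), B, Sk)
        v = self._split(self.v(value), B, Sk)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self._dk))
        if key_padding_mask is not None:
            add = np.where(np.asarray(key_padding_mask, dtype=bool), 0.0, NEG_INF)
            logits = logits + add[:, None, None, :]
        attn = softmax(logits, axis=-1)
        ctx = attn @ v
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Sq, d)
        return self.out(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Dropout:
    """Inverted dropout; identity when ``p == 0`` or no rng is supplied."""

    def __init__(self, p: float):
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if self.p <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer (self-attention + FFN)."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        self.attn = MultiheadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, key_padding_mask=None,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.ln1(x)
        x = x + self.drop(self.attn(h, h, h, key_padding_mask), rng)
        x = x + self.drop(self.ff(self.ln2(x)), rng)
        return x


class DecoderLayer(Module):
    """Pre-norm transformer decoder layer: self-attn, cross-attn, FFN."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        self.self_attn = MultiheadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiheadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)
        self.ln3 = LayerNorm(d_model)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, memory: Tensor, memory_padding_mask=None,
                 query_pos=None, rng: np.random.Generator | None = None) -> Tensor:
        """``query_pos`` (step-identity embedding) is added to the attention
        queries/keys at every layer so step specialization survives depth."""
        h = self.ln1(x)
        hq = h if query_pos is None else h + query_pos
        x = x + self.drop(self.self_attn(hq, hq, h), rng)
        h = self.ln2(x)
        hq = h if query_pos is None else h + query_pos
        x = x + self.drop(self.cross_attn(hq, memory, memory, memory_padding_mask), rng)
        x = x + self.drop(self.ff(self.ln3(x)), rng)
        return x


class MLP(Module):
    """Small ReLU MLP head: d_model -> hidden (x depth) -> d_out."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, depth: int,
                 rng: np.random.Generator):
        dims = [d_in] + [d_hidden] * depth + [d_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


# ---------------------------------------------------------------------------
# Positional encodings (fixed, sinusoidal)
# ---------------------------------------------------------------------------

def sinusoidal_1d(n_pos: int, d_model: int) -> np.ndarray:
    """Standard sine/cosine positional encoding, shape (n_pos, d_model)."""
    pos = np.arange(n_pos, dtype=float)[:, None]
    i = np.arange(d_model // 2, dtype=float)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((n_pos, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def sinusoidal_2d(n_rows: int, n_cols: int, d_model: int) -> np.ndarray:
    """Separable 2-D sine/cosine encoding over a patch grid.

    Half the channels encode the row index and half the column index; the
    result is flattened row-major to ``(n_rows * n_cols, d_model)``.
    """
    if d_model % 2:
        raise ValueError("d_model must be even for the 2-D encoding")
    half = d_model // 2
    row = sinusoidal_1d(n_rows, half)
    col = sinusoidal_1d(n_cols, half)
    pe = np.zeros((n_rows, n_cols, d_model))
    pe[:, :, :half] = row[:, None, :]
    pe[:, :, half:] = col[None, :, :]
    return pe.reshape(n_rows * n_cols, d_model)
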