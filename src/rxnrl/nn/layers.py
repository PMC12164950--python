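"""Neural-network building blocks on the autodiff engine: linear/embedding layers,
layer norm, multi-head attention, and pre-norm transformer encoder/decoder layers."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal container with recursive parameter discovery and state (de)serialization."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state mismatch on keys: {sorted(missing)[:5]} ...")
        for name, t in own.items():
            if t.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            t.data = state[name].copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _init(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor.param(rng.normal(0.0, scale, size=shape))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = _init(rng, d_in, d_out)
        self.b = Tensor.param(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Embedding(Module):
    def __init__(self, n_vocab: int, d_model: int, rng: np.random.Generator):
        self.table = Tensor.param(rng.normal(0.0, 0.02, size=(n_vocab, d_model)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return ad.embedding(self.table, ids)


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gain = Tensor.param(np.ones(d))
        self.bias = Tensor.param(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gain, self.bias)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with `n_heads` heads.

    `mask` is an additive float array broadcastable to (B, heads, Lq, Lk) with 0
    on allowed positions and a large negative value on disallowed ones.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        assert d_model % n_heads == 0
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape((B, L, self.n_heads, self.d_head)).transpose((0, 2, 1, 3))

    def __call__(self, q: Tensor, k: Tensor, v: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, Lq = q.shape[0], q.shape[1]
        Lk = k.shape[1]
        qh = self._split(self.wq(q), B, Lq)
        kh = self._split(self.wk(k), B, Lk)
        vh = self._split(self.wv(v), B, Lk)
        scores = (qh @ kh.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        if mask is not None:
            scores = scores + Tensor(mask)
        attn = ad.softmax(scores, axis=-1)
        ctx = attn @ vh
        ctx = ctx.transpose((0, 2, 1, 3)).reshape((B, Lq, self.n_heads * self.d_head))
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.w1 = Linear(d_model, d_ff, rng)
        self.w2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w2(ad.relu(self.w1(x)))


class EncoderLayer(Module):
    """Pre-norm transformer encoder layer."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, h, mask)
        x = x + self.ff(self.ln2(x))
        return x


class DecoderLayer(Module):
    """Pre-norm transformer decoder layer: causal self-attention + cross-attention."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln3 = LayerNorm(d_model)
        self.ff = FeedForward(d_model, d_ff, rng)

    def __call__(
        self,
        x: Tensor,
        memory: Tensor,
        self_mask: np.ndarray | None,
        cross_mask: np.ndarray | None,
    ) -> Tensor:
        h = self.ln1(x)
        x = x + self.self_attn(h, h, h, self_mask)
        h = self.ln2(x)
        x = x + self.cross_attn(h, memory, memory, cross_mask)
        x = x + self.ff(self.ln3(x))
        return x


NEG_INF = -1e9


def padding_mask(lengths: np.ndarray, max_len: int) -> np.ndarray:
    """(B, 1, 1, L) additive mask hiding positions beyond each sequence's length."""
    idx = np.arange(max_len)[None, :]
    allowed = idx < lengths[:, None]
    return np.where(allowed, 0.0, NEG_INF)[:, None, None, :]


def causal_mask(L: int) -> np.ndarray:
    """(1, 1, L, L) additive mask hiding future positions."""
    m = np.triu(np.full((L, L), NEG_INF), k=1)
    return m[None, None, :, :]
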