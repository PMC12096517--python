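"""Neural-network layers and the Adam optimizer used by the trainable models.

Everything is built on the package's reverse-mode tape (:mod:`._autodiff`),
runs on CPU in float64, and is deterministically initialized from an explicit
``numpy`` generator so that identical seeds give identical training traces.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, softmax

NEG_INF = -1e9


class Module:
    """Base class with recursive parameter collection."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]} ...")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, 1.0, (d_in, d_out)) * scale,
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self._eps).sqrt() * self.gamma + self.beta


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 d_out: int | None = None, zero_init_out: bool = False):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, d_out or dim, rng, zero_init=zero_init_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


def gelu(x: Tensor) -> Tensor:
    # tanh approximation
    return 0.5 * x * (1.0 + (0.7978845608028654 * (x + 0.044715 * x * x * x)).tanh())


class MultiHeadAttention(Module):
    """Self-attention over residues with optional additive pair bias."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 pair_dim: int | None = None):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.pair_proj = Linear(pair_dim, n_heads, rng) if pair_dim else None

    def __call__(self, x: Tensor, pair: Tensor | None = None,
                 mask: np.ndarray | None = None) -> Tensor:
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, *x.shape)
        B, n, dim = x.shape
        h, dh = self.n_heads, self.d_head

        qkv = self.qkv(x).reshape(B, n, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]          # (B, h, n, dh)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        if pair is not None and self.pair_proj is not None:
            bias = self.pair_proj(pair)           # (n, n, h) or (B, n, n, h)
            if bias.ndim == 3:
                logits = logits + bias.transpose(2, 0, 1).reshape(1, h, n, n)
            else:
                logits = logits + bias.transpose(0, 3, 1, 2)
        if mask is not None:
            m = np.asarray(mask, dtype=bool).reshape(B, 1, 1, n)
            logits = logits + Tensor(np.where(m, 0.0, NEG_INF))
        attn = softmax(logits, axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape(B, n, dim)
        out = self.out(out)
        if mask is not None:
            out = out * Tensor(np.asarray(mask, float).reshape(B, n, 1))
        return out.reshape(n, dim) if squeeze else out


class TransformerBlock(Module):
    """Pre-norm attention + MLP block with optional pair bias."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 pair_dim: int | None = None, mlp_ratio: int = 2):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng, pair_dim=pair_dim)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, mlp_ratio * dim, rng)

    def __call__(self, x: Tensor, pair: Tensor | None = None,
                 mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), pair=pair, mask=mask)
        return x + self.mlp(self.norm2(x))


class PairUpdate(Module):
    """Outer-sum update of the pair representation from the single track."""

    def __init__(self, dim: int, pair_dim: int, rng: np.random.Generator):
        self.left = Linear(dim, pair_dim, rng)
        self.right = Linear(dim, pair_dim, rng)
        self.norm = LayerNorm(pair_dim)

    def __call__(self, single: Tensor, pair: Tensor) -> Tensor:
        a = self.left(single)
        b = self.right(single)
        if single.ndim == 2:
            n = single.shape[0]
            outer = a.reshape(n, 1, -1) + b.reshape(1, n, -1)
        else:
            B, n, d = a.shape
            outer = a.reshape(B, n, 1, d) + b.reshape(B, 1, n, d)
        return self.norm(pair + outer)


class DiTBlock(Module):
    """Transformer block with adaptive layer-norm time conditioning."""

    def __init__(self, dim: int, n_heads: int, d_time: int, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, 2 * dim, rng)
        self.modulation = Linear(d_time, 6 * dim, rng, zero_init=True)

    def __call__(self, x: Tensor, t_emb: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, n, dim = x.shape
        mod = self.modulation(t_emb).reshape(B, 1, 6, dim)
        s1, b1, g1 = mod[:, :, 0], mod[:, :, 1], mod[:, :, 2]
        s2, b2, g2 = mod[:, :, 3], mod[:, :, 4], mod[:, :, 5]
        x = x + g1 * self.attn(self.norm1(x) * (1.0 + s1) + b1, mask=mask)
        return x + g2 * self.mlp(self.norm2(x) * (1.0 + s2) + b2)


def sinusoidal_embedding(values: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal features of shape ``(len(values), dim)`` for scalar inputs."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = np.asarray(values, dtype=float).reshape(-1, 1) * freqs
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float((p.grad**2).sum()) for p in self.params.values()
                if p.grad is not None
            ))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
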