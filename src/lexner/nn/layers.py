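"""Neural building blocks: modules, linear/embedding layers, transformer block."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, concat, layer_norm


class Module:
    """Container with recursive parameter discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(xavier_uniform(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out if self.b is None else out + self.b


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.1):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n, d)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight[np.asarray(indices, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float) -> Tensor:
    """softmax(q kᵀ / scale) v — the shared primitive of every attention here."""
    return ((q @ k.T) / scale).softmax(axis=-1) @ v


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Fixed sine/cosine positional code, alternating across the feature axis."""
    pos = np.arange(n)[:, None]
    dim = np.arange(d // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * dim / d)
    out = np.zeros((n, d))
    out[:, 0::2] = np.sin(angle)
    out[:, 1::2] = np.cos(angle)
    return out


class TransformerBlock(Module):
    """Pre-LN self-attention + position-wise feed-forward, both residual."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"hidden size {d} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.ln1 = LayerNorm(d)
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, d_ff, rng)
        self.ff2 = Linear(d_ff, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.ln1(x)
        q, k, v = self.wq(h), self.wk(h), self.wv(h)
        heads = []
        for i in range(self.n_heads):
            sl = slice(i * self.d_head, (i + 1) * self.d_head)
            heads.append(scaled_dot_attention(q[:, sl], k[:, sl], v[:, sl],
                                              np.sqrt(self.d_head)))
        x = x + self.wo(concat(heads, axis=1))
        h = self.ln2(x)
        return x + self.ff2(self.ff1(h).relu())
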