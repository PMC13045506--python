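"""Layer/module system on top of the autodiff tensors.

Mirrors the familiar torch-style API surface (``Module``, ``parameters``,
``train``/``eval``, ``state_dict``) at the scale this package needs.
Construction is fully deterministic: every layer that owns weights receives a
``numpy.random.Generator`` and draws from it in a fixed order, so a single
seed reproduces a model bit-for-bit.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np

from .tensor import (
    Tensor,
    avg_pool2d_to,
    concat,
    conv2d,
    max_pool2d,
    softmax,
)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for mod_name, mod in self.named_modules(prefix):
            for p_name, p in mod._params.items():
                yield (f"{mod_name}.{p_name}" if mod_name else p_name), p

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for mod_name, mod in self.named_modules(prefix):
            for b_name, b in mod._buffers.items():
                yield (f"{mod_name}.{b_name}" if mod_name else b_name), b

    # -- mode -----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, mod in self.named_modules():
            object.__setattr__(mod, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = np.array(b, copy=True)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {name: p for name, p in self.named_parameters()}
        buf_owners = {}
        for mod_name, mod in self.named_modules():
            for b_name in mod._buffers:
                full = f"{mod_name}.{b_name}" if mod_name else b_name
                buf_owners[full] = (mod, b_name)
        missing = (set(own) | set(buf_owners)) - set(state)
        if missing:
            raise KeyError(f"state_dict missing entries: {sorted(missing)[:5]} ...")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.shape}")
            p.data = arr.copy()
        for name, (mod, b_name) in buf_owners.items():
            mod._set_buffer(b_name, np.array(state[name], copy=True))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._order = [str(i) for i in range(len(mods))]

    def forward(self, x):
        for name in self._order:
            x = self._modules[name](x)
        return x

    def __iter__(self):
        return iter(self._modules[n] for n in self._order)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._order: list[str] = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module) -> None:
        name = str(len(self._order))
        setattr(self, name, mod)
        self._order.append(name)

    def __getitem__(self, i: int) -> Module:
        return self._modules[self._order[i]]

    def __len__(self) -> int:
        return len(self._order)

    def __iter__(self):
        return iter(self._modules[n] for n in self._order)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class Conv2d(Module):
    """Convolution with Kaiming-normal (fan-out) weight init, as is standard
    for ReLU CNNs."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_out = kernel * kernel * cout
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride = stride
        self.pad = pad

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(cin)
        self.weight = Parameter(rng.uniform(-bound, bound, (cout, cin)))
        self.bias = Parameter(rng.uniform(-bound, bound, cout)) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class _BatchNorm(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum
        self.num_features = num_features

    def _stats_axes(self, x) -> tuple[int, ...]:
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x) -> tuple[int, ...]:
        return (1, self.num_features) if x.ndim == 2 else (1, self.num_features, 1, 1)

    def forward(self, x):
        axes = self._stats_axes(x)
        shape = self._shape(x)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            n = x.size // self.num_features
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            m = self.momentum
            self._set_buffer("running_mean",
                             (1 - m) * self.running_mean + m * mu.data.reshape(-1))
            self._set_buffer("running_var",
                             (1 - m) * self.running_var + m * unbiased)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class BatchNorm2d(_BatchNorm):
    pass


class BatchNorm1d(_BatchNorm):
    pass


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt() * self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode.  Reseed with
    :func:`seed_dropout` for reproducible training runs."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


def seed_dropout(model: Module, seed: int) -> None:
    """Give every dropout layer an independent, deterministic stream."""
    for i, (_, mod) in enumerate(m for m in model.named_modules() if isinstance(m[1], Dropout)):
        mod.rng = np.random.default_rng(np.random.SeedSequence([seed, i]))


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x):
        return max_pool2d(x, self.kernel, self.stride, self.pad)


class AdaptiveAvgPool2d(Module):
    def __init__(self, out_hw: tuple[int, int] = (1, 1)):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x):
        return avg_pool2d_to(x, self.out_hw)


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % heads:
            raise ValueError(f"model dim {dim} not divisible by {heads} heads")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.in_proj = Linear(dim, 3 * dim, rng=rng)
        self.out_proj = Linear(dim, dim, rng=rng)

    def forward(self, x):
        n, t, c = x.shape
        qkv = self.in_proj(x).reshape(n, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # [3, n, heads, t, head_dim]
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, c)
        return self.out_proj(out)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: x + MHSA(LN(x)); x + FFN(LN(x)), GELU FFN."""

    def __init__(self, dim: int, heads: int, ffn_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = Sequential(Linear(dim, ffn_dim, rng=rng), GELU(),
                              Linear(ffn_dim, dim, rng=rng))

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))
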