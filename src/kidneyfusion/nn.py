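"""Minimal forward-only neural-network layers on NumPy.

The classifiers in this package keep every backbone frozen and train only a
linear head, whose softmax cross-entropy gradient is closed form.  Nothing
here therefore needs automatic differentiation: layers implement ``forward``
only, and parameters are plain arrays with a ``trainable`` flag that the
parameter audit and the optimizer respect.

Shapes follow the channels-first convention ``[B, C, H, W]`` for images and
``[B, N, D]`` for token sequences.
"""

from __future__ import annotations

import zlib
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf


class Param:
    """A parameter array plus its trainability flag."""

    __slots__ = ("data", "trainable")

    def __init__(self, data: np.ndarray, trainable: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.trainable = bool(trainable)

    @property
    def size(self) -> int:
        return int(self.data.size)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        flag = "trainable" if self.trainable else "frozen"
        return f"Param(shape={self.data.shape}, {flag})"


class Module:
    """Base container: auto-registers ``Param`` and ``Module`` attributes."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", False)

    def __setattr__(self, name, value):
        if isinstance(value, Param):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- parameter traversal -------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Param]]:
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.trainable = False
        return self

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialization ---------------------------------------------------
    def state(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self.named_parameters()}

    def load_state(self, mapping: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        unknown = set(mapping) - set(own)
        if unknown:
            raise ValueError(f"unknown parameter names in weights: {sorted(unknown)[:5]}")
        for name, arr in mapping.items():
            arr = np.asarray(arr, dtype=np.float32)
            if arr.shape != own[name].data.shape:
                raise ValueError(
                    f"weight {name!r} has shape {arr.shape}, "
                    f"architecture expects {own[name].data.shape}"
                )
            own[name].data = np.ascontiguousarray(arr)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        self.items = list(mods)
        for i, m in enumerate(self.items):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.items = list(layers)
        for i, m in enumerate(self.items):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def rng_for(name: str, seed: int | None = None) -> np.random.Generator:
    """Deterministic generator keyed on an architecture name (and seed)."""
    key = zlib.crc32(name.encode())
    if seed is None:
        return np.random.default_rng(key)
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _init(rng: np.random.Generator | None, shape, fan_in: int) -> np.ndarray:
    if rng is None:
        return np.zeros(shape, dtype=np.float32)
    std = float(np.sqrt(2.0 / max(fan_in, 1)))
    return rng.standard_normal(shape, dtype=np.float32) * np.float32(std)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(_init(rng, (out_features, in_features), in_features))
        if bias:
            self.bias = Param(np.zeros(out_features, dtype=np.float32))
        else:
            self.bias = None

    def forward(self, x):
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data
        return y


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0, groups: int = 1):
    """Grouped 2-D cross-correlation via strided windows + einsum."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    B, C, Ho, Wo = win.shape[:4]
    cout = w.shape[0]
    cin_g, cout_g = C // groups, cout // groups
    win = win.reshape(B, groups, cin_g, Ho, Wo, kh, kw)
    wg = w.reshape(groups, cout_g, cin_g, kh, kw)
    out = np.einsum("bgchwij,gocij->bgohw", win, wg, optimize=True)
    out = np.ascontiguousarray(out.reshape(B, cout, Ho, Wo))
    if b is not None:
        out += b[None, :, None, None]
    return out


class Conv2d(Module):
    def __init__(self, rng, cin, cout, k, stride=1, pad=0, groups=1, bias=True):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.stride, self.pad, self.groups = stride, pad, groups
        fan_in = (cin // groups) * k * k
        self.weight = Param(_init(rng, (cout, cin // groups, k, k), fan_in))
        self.bias = Param(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        b = self.bias.data if self.bias is not None else None
        return conv2d(x, self.weight.data, b, self.stride, self.pad, self.groups)


class ReLU(Module):
    def forward(self, x):
        return np.maximum(x, 0.0)


class GELU(Module):
    def forward(self, x):
        return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0, dtype=np.float32))).astype(x.dtype)


class LayerNorm(Module):
    """Normalizes over the trailing axis."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Param(np.ones(dim, dtype=np.float32))
        self.bias = Param(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        y = (x - mu) / np.sqrt(var + self.eps)
        return y * self.weight.data + self.bias.data


class LayerNorm2d(LayerNorm):
    """LayerNorm over the channel axis of a [B, C, H, W] tensor."""

    def forward(self, x):
        y = super().forward(np.moveaxis(x, 1, -1))
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x):
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        return win.max(axis=(-2, -1))


def _adaptive_pool(x, out_hw, reduce_fn):
    B, C, H, W = x.shape
    oh, ow = out_hw
    hb = [(H * i) // oh for i in range(oh + 1)]
    wb = [(W * j) // ow for j in range(ow + 1)]
    out = np.empty((B, C, oh, ow), dtype=x.dtype)
    for i in range(oh):
        for j in range(ow):
            out[:, :, i, j] = reduce_fn(x[:, :, hb[i]:hb[i + 1], wb[j]:wb[j + 1]])
    return out


class AdaptiveAvgPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x):
        return _adaptive_pool(x, self.out_hw, lambda v: v.mean(axis=(2, 3)))


class AdaptiveMaxPool2d(Module):
    def __init__(self, out_hw: tuple[int, int]):
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x):
        return _adaptive_pool(x, self.out_hw, lambda v: v.max(axis=(2, 3)))


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], -1)


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Own generator, reseeded by
    ``train()`` callers through :meth:`reseed` for reproducible epochs."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self._rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def forward(self, x):
        if not self.training or self.p <= 0.0:
            return x
        keep = (self._rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * keep / (1.0 - self.p)


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiheadSelfAttention(Module):
    """Standard multi-head self-attention over [B, N, D] tokens.

    ``attn_bias`` (additive, broadcastable to [B, heads, N, N]) carries
    relative-position terms and window masks for the hierarchical models.
    """

    def __init__(self, rng, dim: int, heads: int, qkv_bias: bool = True):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(rng, dim, 3 * dim, bias=qkv_bias)
        self.proj = Linear(rng, dim, dim)

    def forward(self, x, attn_bias=None):
        B, N, D = x.shape
        qkv = self.qkv(x).reshape(B, N, 3, self.heads, self.head_dim)
        q, k, v = (np.moveaxis(qkv[:, :, i], 1, 2) for i in range(3))  # [B,H,N,hd]
        attn = (q @ np.swapaxes(k, -2, -1)) * self.scale
        if attn_bias is not None:
            attn = attn + attn_bias
        attn = softmax(attn, axis=-1)
        out = np.moveaxis(attn @ v, 1, 2).reshape(B, N, D)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, rng, dim: int, hidden: int):
        super().__init__()
        self.fc1 = Linear(rng, dim, hidden)
        self.act = GELU()
        self.fc2 = Linear(rng, hidden, dim)

    def forward(self, x):
        return self.fc2(self.act(self.fc1(x)))
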