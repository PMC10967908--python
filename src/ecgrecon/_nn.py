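"""Neural-network building blocks on top of the autodiff core.

Layers hold :class:`~ecgrecon._autograd.Tensor` parameters; ``Module``
provides recursive parameter discovery, state (de)serialization and seeded
initialization.  Initialization draws come from the ``numpy`` generator
passed to each layer, so a model is fully determined by its config and seed.
"""

from __future__ import annotations

import math

import numpy as np

from ._autograd import Tensor

__all__ = ["Module", "Linear", "Conv1d", "Conv2d", "LayerNorm", "Dropout", "Adam"]


class Module:
    """Base class: recursive parameter traversal + flat state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                named.append((key, value))
            elif isinstance(value, Module):
                named.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        named.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        named.append((f"{key}.{i}", item))
        return named

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: np.array(p.data, copy=True) for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = np.array(arr, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, (in_features, out_features), in_features, out_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Length-preserving 1-D convolution, kernel (K, Cin, Cout), K odd."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        fan_in = kernel_size * in_channels
        self.weight = Tensor(
            _glorot(rng, (kernel_size, in_channels, out_channels), fan_in, out_channels),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias)


class Conv2d(Module):
    """Shape-preserving 2-D convolution, kernel (kh, kw, Cin, Cout)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        kh = kw = kernel_size
        fan_in = kh * kw * in_channels
        self.weight = Tensor(
            _glorot(rng, (kh, kw, in_channels, out_channels), fan_in, out_channels),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)


class LayerNorm(Module):
    """Normalize the trailing feature axis to zero mean / unit variance."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gain + self.bias

    def normalize(self, x: Tensor) -> Tensor:
        """Pre-affine normalization (diagnostics / tests)."""
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt()


class Dropout(Module):
    """Inverted dropout; identity when ``train=False`` or p == 0."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator, train: bool) -> Tensor:
        if not train or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class Adam:
    """Adam optimizer with optional global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 1.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
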