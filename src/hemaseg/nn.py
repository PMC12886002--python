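"""Neural-network layers and the AdamW optimizer on top of :mod:`hemaseg.autodiff`."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv2d


class Module:
    """Base class; parameters are discovered by attribute introspection."""

    def named_parameters(self, prefix: str = ""):
        # every Tensor attribute is a parameter (frozen ones stay listed so
        # checkpoints and freeze checks see them); constants are kept as
        # plain numpy arrays by convention
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_trainable(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag


def parameter(data) -> Tensor:
    t = Tensor(data, requires_grad=True)
    return t


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.weight = parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = math.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.weight = parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = parameter(np.ones(dim))
        self.beta = parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gamma + self.beta


class AdamW:
    """Adam with decoupled weight decay; skips parameters frozen after creation."""

    def __init__(self, params, lr: float = 3e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + self.weight_decay * p.data)
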