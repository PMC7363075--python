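"""Layer and module abstractions over the autodiff tensors."""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, batchnorm, conv_nd, dropout, matmul

__all__ = ["Module", "Conv", "Dense", "BatchNorm", "Dropout", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class; collects parameters and persistent buffers recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            params.extend(_collect_params(v))
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            _collect_state(v, f"{prefix}{name}", state)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            _load_state(v, f"{prefix}{name}", state)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect_params(v):
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_params(item))
        return out
    return []


def _collect_state(v, key, state):
    if isinstance(v, Tensor) and v.requires_grad:
        state[key] = v.data
    elif isinstance(v, np.ndarray):
        state[key] = v
    elif isinstance(v, Module):
        for name, sub in vars(v).items():
            _collect_state(sub, f"{key}.{name}", state)
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            _collect_state(item, f"{key}.{i}", state)


def _load_state(v, key, state):
    if isinstance(v, Tensor) and v.requires_grad:
        v.data = state[key].astype(np.float32).reshape(v.data.shape)
    elif isinstance(v, np.ndarray):
        v[...] = state[key]
    elif isinstance(v, Module):
        for name, sub in vars(v).items():
            _load_state(sub, f"{key}.{name}", state)
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            _load_state(item, f"{key}.{i}", state)


class Conv(Module):
    """Stride-1 "same" convolution; glorot-uniform weights, zero biases."""

    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator):
        kernel = tuple(kernel)
        ksize = int(np.prod(kernel))
        w = glorot_uniform(rng, (out_ch, in_ch) + kernel,
                           fan_in=in_ch * ksize, fan_out=out_ch * ksize)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.w, self.b)


class Dense(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        w = glorot_uniform(rng, (in_f, out_f), fan_in=in_f, fan_out=out_f)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(out_f, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class BatchNorm(Module):
    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return batchnorm(x, self.gamma, self.beta, self.running_mean,
                         self.running_var, self.momentum, self.eps, training)


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        return dropout(x, self.rate, rng, training)
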