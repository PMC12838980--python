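"""Layer library for the dual-attention CNN.

Thin ``Module`` abstraction over :mod:`painattn.autodiff`: convolution,
linear, batch normalization (1-D and 2-D), dropout. Parameter
initialization follows the He scheme for ReLU stacks and is driven by an
explicit ``numpy.random.Generator`` so models are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d

__all__ = ["Module", "Conv2d", "Linear", "BatchNorm", "Dropout", "MaxPool2d"]


class Module:
    """Base class: tracks parameters, training mode, child modules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in getattr(self, "_buffers", {}).items()]
        for cname, child in self._children.items():
            out.extend(child.buffers(prefix + cname + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, b in self.buffers():
            state["buffer." + n] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float32).reshape(p.data.shape)
        for n, b in self.buffers():
            b[...] = np.asarray(state["buffer." + n], dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 1, bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.padding = padding
        self.register("weight", rng.normal(
            0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = None
        if bias:
            self.register("bias", np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.register("weight", rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = None
        if bias:
            self.register("bias", np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm(Module):
    """Batch normalization over (N,) or (N,H,W) statistics per channel.

    ``spatial=True`` expects NCHW input, otherwise NxF.
    """

    def __init__(self, num_features: int, spatial: bool, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.spatial = spatial
        self.eps = eps
        self.momentum = momentum
        self.register("gamma", np.ones(num_features))
        self.register("beta", np.zeros(num_features))
        self._buffers = {
            "running_mean": np.zeros(num_features, dtype=np.float32),
            "running_var": np.ones(num_features, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3) if self.spatial else (0,)
        shape = (1, -1, 1, 1) if self.spatial else (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1.0 - self.momentum
            rm += self.momentum * mu.data.reshape(-1)
            rv *= 1.0 - self.momentum
            rv += self.momentum * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class Dropout(Module):
    """Inverted dropout; draws its mask from the generator passed at call."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        mask = (rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.size)
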