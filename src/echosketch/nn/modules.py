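"""Minimal layer/module system with explicit backprop.

Conventions:
- every Module caches what its most recent ``forward`` needs for ``backward``;
  backward must therefore be called on the forward that immediately preceded it
  (the training loops in :mod:`echosketch.training` respect this),
- ``backward`` accumulates parameter gradients (call ``zero_grad`` between
  optimisation steps) and returns the gradient w.r.t. its input,
- parameters are float64 numpy arrays, images live in [-1, 1].
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Identity",
    "Sequential",
]


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class; subclasses populate ``_params`` and ``_children``."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    # -- structure ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield (prefix + name, p)
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- state -------------------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        for name, buf in getattr(self, "_buffers", {}).items():
            out[prefix + name] = buf.copy()
        for cname, child in self._children.items():
            out.update(child.state_dict(prefix + cname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True) -> list[str]:
        """Load matching entries; returns the names that were skipped."""
        own = self._flat_slots()
        skipped = []
        for name, slot in own.items():
            if name not in state:
                if strict:
                    raise KeyError(f"missing parameter {name!r} in state dict")
                skipped.append(name)
                continue
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != slot.shape:
                if strict:
                    raise ValueError(
                        f"shape mismatch for {name!r}: {arr.shape} vs {slot.shape}"
                    )
                skipped.append(name)
                continue
            slot[...] = arr
        return skipped

    def _flat_slots(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {name: p.data for name, p in self._params.items()}
        out.update({name: buf for name, buf in getattr(self, "_buffers", {}).items()})
        out = {prefix + k: v for k, v in out.items()}
        for cname, child in self._children.items():
            out.update(child._flat_slots(prefix + cname + "."))
        return out

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_channels * kernel * kernel
        self._params["weight"] = Parameter(
            _he_init(rng, (out_channels, in_channels, kernel, kernel), fan_in)
        )
        self._params["bias"] = Parameter(np.zeros(out_channels))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = F.conv_forward(x, self._params["weight"].data, self.stride, self.padding)
        return y + self._params["bias"].data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self._params["weight"]
        w.grad += F.conv_weight_grad(self._x, dy, self.kernel, self.stride, self.padding)
        self._params["bias"].grad += dy.sum(axis=(0, 2, 3))
        return F.conv_input_grad(
            dy, w.data, self.stride, self.padding, self._x.shape[2:]
        )


class ConvTranspose2d(Module):
    """Transposed convolution; weight layout (in_channels, out_channels, k, k)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.kernel = stride, padding, kernel
        fan_in = in_channels * kernel * kernel
        self._params["weight"] = Parameter(
            _he_init(rng, (in_channels, out_channels, kernel, kernel), fan_in)
        )
        self._params["bias"] = Parameter(np.zeros(out_channels))
        self._x: np.ndarray | None = None

    def out_size(self, size: int) -> int:
        return (size - 1) * self.stride - 2 * self.padding + self.kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        h, w = x.shape[2:]
        y = F.conv_input_grad(
            x,
            self._params["weight"].data,
            self.stride,
            self.padding,
            (self.out_size(h), self.out_size(w)),
        )
        return y + self._params["bias"].data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w = self._params["weight"]
        # The transpose of conv's input-grad is conv's forward; weight grad
        # swaps the roles of input and output grad.
        w.grad += F.conv_weight_grad(dy, self._x, self.kernel, self.stride, self.padding)
        self._params["bias"].grad += dy.sum(axis=(0, 2, 3))
        return F.conv_forward(dy, w.data, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self._params["gamma"] = Parameter(np.ones(channels))
        self._params["beta"] = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        g = self._params["gamma"].data
        b = self._params["beta"].data
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mean
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return g[None, :, None, None] * xhat + b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        g = self._params["gamma"].data
        n = shape[0] * shape[2] * shape[3]
        self._params["gamma"].grad += (dy * xhat).sum(axis=(0, 2, 3))
        self._params["beta"].grad += dy.sum(axis=(0, 2, 3))
        if not self.training:
            return dy * (g * inv)[None, :, None, None]
        del n
        dxhat = dy * g[None, :, None, None]
        m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (dxhat - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Tanh(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Identity(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(self.layers):
            self._children[str(i)] = layer

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
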