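"""Layer containers built on :mod:`renalseg.nn.tensor`.

The API intentionally mirrors the conventions of mainstream deep-learning
frameworks (``Module``, ``parameters``, ``state_dict``) so the network code
reads familiarly, while staying a few hundred lines of numpy.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: child modules/parameters are discovered via ``__dict__``."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization ----------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(prefix=f"{path}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{params[name].data.shape} vs {value.shape}")
                params[name].data = np.asarray(value, dtype=T.DTYPE).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 2D convolution with He-normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale,
                                           (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization.

    ``identity=True`` bypasses the layer entirely; this mode exists so the
    residual-block algebra can be verified analytically in tests.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 identity: bool = False):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps = eps
        self.momentum = momentum
        self.identity = identity

    def forward(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        if self.training:
            mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = T.tmean(T.power(x - mu, 2.0), axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = (x - mu) / T.sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mu) / np.sqrt(var + self.eps)
        return T.add(T.mul(xhat, T.reshape(self.gamma, (1, -1, 1, 1))),
                     T.reshape(self.beta, (1, -1, 1, 1)))
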