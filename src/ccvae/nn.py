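"""Neural-network layers and the Adam optimizer on top of :mod:`ccvae.autodiff`.

Layers hold their parameters as ``Tensor`` objects with ``requires_grad=True``
and are initialized from an explicit numpy ``Generator`` so that model builds
are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid",
           "Flatten", "Sequential", "Upsample", "MaxPool2d", "Adam"]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def __call__(self, x):
        return self.forward(x)

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        seen = set()
        for mod in self.modules():
            for value in mod.__dict__.values():
                if isinstance(value, Tensor) and value.requires_grad \
                        and id(value) not in seen:
                    seen.add(id(value))
                    yield value

    def named_state(self, prefix=""):
        """All arrays (parameters and buffers) keyed by dotted path."""
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield key, value
            elif isinstance(value, np.ndarray):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_state(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_state(prefix=f"{key}.{i}.")

    def state_dict(self):
        out = {}
        for key, value in self.named_state():
            out[key] = value.data.copy() if isinstance(value, Tensor) else value.copy()
        return out

    def load_state_dict(self, state):
        own = dict(self.named_state())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} "
                             f"unexpected={sorted(extra)}")
        for key, value in own.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if isinstance(value, Tensor):
                if value.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                value.data = arr.copy()
            else:
                if value.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                value[...] = arr

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, bound, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, k, k)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization composed from differentiable primitives.

    Training mode normalizes with batch statistics and updates running
    moments; eval mode normalizes with the stored running moments.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, num_features, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_features, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, num_features, 1, 1))
        self.running_var = np.ones((1, num_features, 1, 1))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - Tensor(self.running_mean)) \
                * Tensor((self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x):
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return x.upsample_nearest2d(self.scale)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return x.maxpool2d(self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
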