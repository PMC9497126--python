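"""Neural-network building blocks over the autodiff engine.

Modules hold named parameters (Tensors with requires_grad=True) and optional
buffers (plain ndarrays, e.g. batch-norm running statistics). A module tree
is (de)serialisable to flat dicts of numpy arrays for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d, maxpool2x2

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "Dropout",
    "MaxPool2x2",
    "ELU",
    "Sequential",
]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data.copy()
        for k, v in self._buffers.items():
            out[prefix + "buf." + k] = np.asarray(v).copy()
        for name, child in self._children.items():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, v in self._params.items():
            v.data = np.asarray(state[prefix + k], dtype=np.float32).copy()
        for k in list(self._buffers):
            self._buffers[k] = np.asarray(state[prefix + "buf." + k]).copy()
            object.__setattr__(self, k, self._buffers[k])
        for name, child in self._children.items():
            child.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        self.padding = (k // 2) if padding is None else padding
        self.w = self.register_parameter(
            "w", _he_init(rng, (cout, cin, k, k), cin * k * k)
        )
        self.b = self.register_parameter("b", np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, padding=self.padding)


class ConvTranspose2x2(Module):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.register_parameter("w", _he_init(rng, (cin, cout, 2, 2), cin * 4))
        self.b = self.register_parameter("b", np.zeros(cout, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = self.register_parameter("gamma", np.ones(c, np.float32))
        self.beta = self.register_parameter("beta", np.zeros(c, np.float32))
        self.running_mean = self.register_buffer("running_mean", np.zeros(c, np.float32))
        self.running_var = self.register_buffer("running_var", np.ones(c, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[:] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[:] = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - mu) * inv[None, :, None, None]
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Dropout(Module):
    """Inverted dropout; the mask rng comes from the trainer for determinism."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * mask


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class ELU(Module):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x: Tensor) -> Tensor:
        return x.elu(self.alpha)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
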