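"""Layer modules built on the autodiff primitives.

Parameters are He-normal initialized (the standard for ReLU networks) from
a module-owned Generator so weight draws are reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (Tensor, batchnorm2d, conv2d, conv_transpose2x2,
                       maxpool2x2, upsample_bilinear2x)

__all__ = ["Module", "Conv2d", "ConvTranspose2x2", "BatchNorm2d",
           "ReLU", "Sigmoid", "MaxPool2x2", "UpsampleBilinear2x",
           "Sequential", "ConvBlock"]


class Module:
    """Base class: parameter registry, train/eval mode, state (de)serialization."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def named_parameters(self, prefix: str = ""):
        for k, v in self._params.items():
            yield f"{prefix}{k}", v
        for mk, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{mk}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for k, v in self._buffers.items():
            yield f"{prefix}{k}", v
        for mk, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{mk}.")

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        out.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for k, v in state.items():
            if k.startswith("buffer:"):
                buf = buffers[k[len("buffer:"):]]
                buf[...] = v
            else:
                params[k].data[...] = v

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: tuple[int, int] | int,
                 stride: tuple[int, int] = (1, 1),
                 padding: tuple[int, int] | str = "same",
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        kh, kw = kernel
        if padding == "same":
            padding = (kh // 2, kw // 2)
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng()
        fan_in = cin * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, kh, kw))
        self.w = self.register_parameter("w", w)
        self.b = self.register_parameter("b", np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.padding)


class ConvTranspose2x2(Module):
    """2x2 stride-2 up-convolution (doubles spatial dims)."""

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout, 2, 2))
        self.w = self.register_parameter("w", w)
        self.b = self.register_parameter("b", np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.register_parameter("gamma", np.ones(channels))
        self.beta = self.register_parameter("beta", np.zeros(channels))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels))
        self.running_var = self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        return batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                           self.running_var, self.training,
                           self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return maxpool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return upsample_bilinear2x(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class ConvBlock(Module):
    """conv -> BN -> ReLU with an identity residual shortcut.

    A 1x1 projection aligns channels when they differ; the shortcut is
    added before the ReLU.
    """

    def __init__(self, cin: int, cout: int, kernel=3, residual: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.residual = residual
        self.proj = None
        if residual and cin != cout:
            self.proj = Conv2d(cin, cout, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        if self.residual:
            shortcut = self.proj(x) if self.proj is not None else x
            y = y + shortcut
        return y.relu()
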