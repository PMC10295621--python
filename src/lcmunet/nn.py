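"""Layer abstractions over the autograd core: modules, convolutions, norms.

Initialisation follows the Kaiming-uniform convention (bound 1/sqrt(fan_in))
so randomly built networks train out of the box.  Every layer takes an
explicit ``rng`` so whole models are a pure function of one integer seed.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Parameter, Tensor


class Module:
    """Base class with recursive parameter registration and train/eval state."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._mods.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._mods.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._mods.values():
            yield from m.modules()

    # -- state ---------------------------------------------------------------
    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({"buffer:" + k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for k, v in state.items():
            if k.startswith("buffer:"):
                buf = buffers[k[len("buffer:"):]]
                buf[...] = v
            else:
                if params[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                params[k].data[...] = v

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._seq = list(mods)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """2-D convolution; ``padding='same'`` keeps spatial size at stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 *, stride: int = 1, padding="same", groups: int = 1,
                 bias: bool = False, rng: np.random.Generator):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if in_channels % groups or out_channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = (kh, kw)
        self.stride, self.groups = stride, groups
        self.padding = ((kh - 1) // 2, (kw - 1) // 2) if padding == "same" else padding
        fan_in = in_channels // groups * kh * kw
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels // groups, kh, kw), fan_in))
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (the classic UNet up-step)."""

    def __init__(self, in_channels: int, out_channels: int, *,
                 bias: bool = True, rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * 4
        self.weight = Parameter(_kaiming_uniform(
            rng, (in_channels, out_channels, 2, 2), fan_in))
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 bias: bool = True, rng: np.random.Generator):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_features, in_features), in_features))
        self.bias = Parameter(_kaiming_uniform(rng, (out_features,), in_features)) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm2d(x, self.weight, self.bias,
                              self.running_mean, self.running_var,
                              training=self.training,
                              momentum=self.momentum, eps=self.eps)


class LayerNormChannels(Module):
    """Layer normalisation over the channel axis of NCHW feature maps."""

    def __init__(self, channels: int, *, eps: float = 1e-5):
        super().__init__()
        self.channels, self.eps = channels, eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.layer_norm_channels(x, self.weight, self.bias, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        return T.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return T.max_pool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return T.upsample_bilinear2x(x)
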