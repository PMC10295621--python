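"""Building blocks of the lightweight CNN+MLP segmentation network.

Three units make up the network body:

* **LDA-A** — a two-part convolutional block.  Part I maps channels with a
  1x1 convolution, refines spatially with a depthwise convolution, and adds
  a batch-normalised 1x1 projection of the input.  Part II mixes channels
  with a second 1x1 convolution, applies a depthwise asymmetric pair
  (1xk then kx1), and adds a depthwise-convolved shortcut of the Part-I
  output.  The block output adds the projected input once more as a
  residual.  All convolutions run at the input resolution; when the block
  is configured with stride 2 a 2x2 max-pool closes the stage.
* **LDA-B** — LDA-A with squeeze-and-excitation channel attention applied
  to the Part-I output (after the first ADD).
* **LMLP** — an axial tokenized-MLP block: a 1x1 tokenizer, a shift of
  channel groups along the width followed by a per-token MLP and a
  depthwise convolution, the same along the height, two optional ADD
  fusions, a residual connection, and layer normalisation at the output.

Feature fusion throughout is elementwise addition — never concatenation —
so a block's output channel count is exactly its configured width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .nn import (GELU, BatchNorm2d, Conv2d, LayerNormChannels, Linear,
                 MaxPool2x2, Module, ReLU, Sequential, Sigmoid)
from .tensor import Tensor


def default_se_reduction(channels: int) -> int:
    """Squeeze-and-excitation bottleneck ratio: gentler for narrow stages."""
    return 2 if channels <= 128 else 4


@dataclass
class LdaConfig:
    """Hyperparameters of one LDA block.

    ``stride`` is the stage resampling factor: 2 appends a 2x2 max-pool.
    ``kernel_size`` is the depthwise kernel; ``asym_kernel`` the length of
    the 1xk / kx1 asymmetric pair; ``shortcut_kernel`` the depthwise kernel
    of the Part-II shortcut.
    """

    in_channels: int
    out_channels: int
    stride: int = 1
    use_se: bool = False
    se_reduction: int | None = None
    kernel_size: int = 5
    asym_kernel: int = 5
    shortcut_kernel: int = 3

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.use_se:
            if self.se_reduction is None:
                self.se_reduction = default_se_reduction(self.out_channels)
            if self.out_channels % self.se_reduction:
                raise ValueError(
                    f"out_channels={self.out_channels} not divisible by "
                    f"se_reduction={self.se_reduction}")


@dataclass
class LmlpConfig:
    channels: int
    token_hidden_ratio: float = 0.25
    shift_size: int = 1
    dw_kernel: int = 3
    enable_add1: bool = True
    enable_add2: bool = True

    def __post_init__(self):
        if self.channels <= 0:
            raise ValueError("channels must be positive")
        if self.token_hidden_ratio <= 0:
            raise ValueError("token_hidden_ratio must be positive")
        if self.shift_size < 0:
            raise ValueError("shift_size must be non-negative")

    @property
    def hidden(self) -> int:
        return max(1, int(round(self.token_hidden_ratio * self.channels)))


class DepthwiseSeparableConv(Module):
    """Per-channel kxk convolution then 1x1 pointwise mixing, BN after each."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 *, rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        self.depthwise = Conv2d(in_channels, in_channels, kernel_size,
                                groups=in_channels, rng=rng)
        self.bn1 = BatchNorm2d(in_channels)
        self.pointwise = Conv2d(in_channels, out_channels, 1, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} channels, got {x.shape[1]}")
        return self.bn2(self.pointwise(self.bn1(self.depthwise(x))))


class AsymmetricConvPair(Module):
    """A 1xk convolution followed by a kx1 convolution, BN after each.

    ``depthwise=False`` gives the full (cross-channel) pair; the LDA blocks
    use the per-channel variant, which costs 2k weights per channel.
    """

    def __init__(self, channels: int, kernel: int = 3, *,
                 depthwise: bool = False, batch_norm: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        g = channels if depthwise else 1
        self.conv_1xk = Conv2d(channels, channels, (1, kernel), groups=g, rng=rng)
        self.conv_kx1 = Conv2d(channels, channels, (kernel, 1), groups=g, rng=rng)
        self.bn1 = BatchNorm2d(channels) if batch_norm else None
        self.bn2 = BatchNorm2d(channels) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        y = self.conv_1xk(x)
        if self.bn1 is not None:
            y = self.bn1(y)
        y = self.conv_kx1(y)
        if self.bn2 is not None:
            y = self.bn2(y)
        return y


class SqueezeExcite(Module):
    """Channel attention: global average squeeze, bottleneck MLP excitation.

    The squeeze is the per-channel spatial mean; excitation is
    ``sigmoid(W2 relu(W1 z))`` with W1: C -> C/r and W2: C/r -> C; the input
    is rescaled per channel by the resulting weights in [0, 1], so the
    output never exceeds the input in magnitude.
    """

    def __init__(self, channels: int, reduction: int, *, rng: np.random.Generator):
        super().__init__()
        if reduction < 1 or channels % reduction:
            raise ValueError(
                f"channels={channels} must be divisible by reduction={reduction}")
        self.channels, self.reduction = channels, reduction
        self.fc1 = Linear(channels, channels // reduction, rng=rng)
        self.fc2 = Linear(channels // reduction, channels, rng=rng)

    def squeeze(self, x: Tensor) -> Tensor:
        return T.global_avg_pool(x)

    def excite(self, z: Tensor) -> Tensor:
        return T.sigmoid(self.fc2(T.relu(self.fc1(z))))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return T.scale_channels(x, self.excite(self.squeeze(x)))


class LDABlock(Module):
    """The LDA block; ``cfg.use_se`` switches between the A and B variants."""

    def __init__(self, cfg: LdaConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        a, b = cfg.in_channels, cfg.out_channels
        # Part I
        self.conv1 = Conv2d(a, b, 1, rng=rng)
        self.bn1 = BatchNorm2d(b)
        self.dwconv = Conv2d(b, b, cfg.kernel_size, groups=b, rng=rng)
        self.bn_dw = BatchNorm2d(b)
        self.shortcut = Conv2d(a, b, 1, rng=rng)       # projection of X
        self.bn_shortcut = BatchNorm2d(b)
        self.se = SqueezeExcite(b, cfg.se_reduction, rng=rng) if cfg.use_se else None
        # Part II
        self.conv2 = Conv2d(b, b, 1, rng=rng)
        self.bn2 = BatchNorm2d(b)
        self.asym = AsymmetricConvPair(b, cfg.asym_kernel, depthwise=True, rng=rng)
        self.shortcut2 = Conv2d(b, b, cfg.shortcut_kernel, groups=b, rng=rng)
        self.bn_shortcut2 = BatchNorm2d(b)
        self.pool = MaxPool2x2() if cfg.stride == 2 else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        proj = self.bn_shortcut(self.shortcut(x))
        po1 = T.relu(self.bn1(self.conv1(x)))
        po2 = self.bn_dw(self.dwconv(po1))
        po3 = T.relu(po2 + proj)
        if self.se is not None:
            po3 = self.se(po3)
        pt1 = T.relu(self.bn2(self.conv2(po3)))
        pt3 = self.asym(pt1)
        pt4 = pt3 + self.bn_shortcut2(self.shortcut2(po3))
        y = T.relu(pt4 + proj)
        if self.pool is not None:
            y = self.pool(y)
        return y


class TokenMLP(Module):
    """Per-token channel MLP (1x1 conv -> GELU -> 1x1 conv, with biases)."""

    def __init__(self, channels: int, hidden: int, *, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Conv2d(channels, hidden, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(T.gelu(self.fc1(x)))


def _shift_offsets(channels: int, shift_size: int) -> np.ndarray:
    """Channels split in 5 groups shifted by shift_size * (-2..2) pixels."""
    groups = np.array_split(np.arange(channels), 5)
    offsets = np.zeros(channels, dtype=np.int64)
    for g, step in zip(groups, (-2, -1, 0, 1, 2)):
        offsets[g] = step * shift_size
    return offsets


class LMLPBlock(Module):
    """Axial shifted token-MLP block; shape- and channel-preserving."""

    def __init__(self, cfg: LmlpConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, h = cfg.channels, cfg.hidden
        self.tokenize = Conv2d(c, c, 1, bias=True, rng=rng)
        self.mlp_w = TokenMLP(c, h, rng=rng)
        self.dw1 = Conv2d(c, c, cfg.dw_kernel, groups=c, bias=True, rng=rng)
        self.mlp_h = TokenMLP(c, h, rng=rng)
        self.dw2 = Conv2d(c, c, cfg.dw_kernel, groups=c, bias=True, rng=rng)
        self.norm = LayerNormChannels(c)
        self._offsets = _shift_offsets(c, cfg.shift_size)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.shape[1] != cfg.channels:
            raise ValueError(f"expected {cfg.channels} channels, got {x.shape[1]}")
        if cfg.shift_size >= min(x.shape[2], x.shape[3]):
            raise ValueError("shift exceeds the spatial extent at this stage")
        xt = self.tokenize(T.axial_shift(x, self._offsets, axis=3))
        yw1 = self.mlp_w(xt)
        yw2 = self.dw1(yw1)
        yw3 = yw2 + xt if cfg.enable_add1 else yw2
        yh1 = self.mlp_h(T.axial_shift(yw3, self._offsets, axis=2))
        yh2 = self.dw2(yh1)
        yh3 = yw3 + yh2 if cfg.enable_add2 else yh2
        return self.norm(x + yh3)
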