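"""Assembly of the 16-stage encoder-decoder and its ablation variants.

The canonical model follows a fixed stage table: a 5-level encoder
(LDA-A 3->16, LDA-B 16->32, LDA-B 32->128, then two tokenized-MLP levels
128->160 and 160->256, each halving resolution) mirrored by a decoder that
upsamples bilinearly after every stage and fuses same-resolution encoder
features by elementwise addition after a 1x1 channel-matching convolution.
Channel width is capped at 256.  The head is a 1x1 convolution to a single
channel followed by a sigmoid, producing a per-pixel foreground probability.

``build_variant`` also provides the ablation models (every block stage as
LDA-A; LDA-B everywhere but the first level; LDA-A conv levels with MLP
levels kept) and a classic 5-level UNet baseline for complexity comparison.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .blocks import LDABlock, LdaConfig, LMLPBlock, LmlpConfig
from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2x2, Module,
                 ReLU, Sequential, UpsampleBilinear2x)
from .tensor import Tensor

VARIANTS = ("lcmunet", "all_lda_a", "lda_a_plus_b", "lda_a_plus_lmlp",
            "unet_baseline")


@dataclass(frozen=True)
class StageSpec:
    index: int
    kind: str                 # LDA-A | LDA-B | LMLP | BilinearUp | Head
    in_channels: int
    out_channels: int
    scale: int                # stage resampling factor (2 = halve/double)


@dataclass(frozen=True)
class SkipPlan:
    """Encoder stage -> decoder (upsample) stage pairs fused by add."""

    pairs: tuple[tuple[int, int], ...] = ((4, 7), (3, 9), (2, 11), (1, 13))


@dataclass
class ArchitectureSpec:
    stages: list[StageSpec]
    skips: SkipPlan = field(default_factory=SkipPlan)

    def fingerprint(self) -> str:
        payload = json.dumps(
            [[s.index, s.kind, s.in_channels, s.out_channels, s.scale]
             for s in self.stages] + [list(map(list, self.skips.pairs))])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_CANONICAL_ROWS = [
    (1, "LDA-A", 3, 16, 2), (2, "LDA-B", 16, 32, 2), (3, "LDA-B", 32, 128, 2),
    (4, "LMLP", 128, 160, 2), (5, "LMLP", 160, 256, 2),
    (6, "LMLP", 256, 160, 1), (7, "BilinearUp", 160, 160, 2),
    (8, "LMLP", 160, 128, 1), (9, "BilinearUp", 128, 128, 2),
    (10, "LDA-B", 128, 32, 1), (11, "BilinearUp", 32, 32, 2),
    (12, "LDA-B", 32, 16, 1), (13, "BilinearUp", 16, 16, 2),
    (14, "LDA-A", 16, 3, 1), (15, "BilinearUp", 3, 3, 2),
    (16, "Head", 3, 1, 1),
]


def canonical_spec() -> ArchitectureSpec:
    return ArchitectureSpec([StageSpec(*row) for row in _CANONICAL_ROWS])


def variant_spec(name: str) -> ArchitectureSpec:
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid: {', '.join(VARIANTS)}")
    if name == "unet_baseline":
        raise ValueError("unet_baseline has no stage table; use build_variant")
    spec = canonical_spec()
    if name == "lcmunet":
        return spec

    def remap(s: StageSpec) -> StageSpec:
        if s.kind in ("BilinearUp", "Head"):
            return s
        if name == "all_lda_a":
            kind = "LDA-A"
        elif name == "lda_a_plus_b":
            kind = "LDA-A" if s.index in (1, 16 - 2) else "LDA-B"
        else:  # lda_a_plus_lmlp
            kind = s.kind if s.kind == "LMLP" else "LDA-A"
        return StageSpec(s.index, kind, s.in_channels, s.out_channels, s.scale)
    return ArchitectureSpec([remap(s) for s in spec.stages], spec.skips)


class _EmbeddedLMLP(Module):
    """Patch-embedding 3x3 convolution (stride 2 in the encoder) + LMLP."""

    def __init__(self, in_channels: int, out_channels: int, stride: int, *,
                 rng: np.random.Generator, lmlp_kwargs: dict | None = None):
        super().__init__()
        self.embed = Conv2d(in_channels, out_channels, 3, stride=stride, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.block = LMLPBlock(LmlpConfig(out_channels, **(lmlp_kwargs or {})),
                               rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block(T.relu(self.bn(self.embed(x))))


class _Head(Module):
    """1x1 conv + sigmoid head.

    The bias starts at the background-prior logit (-2, i.e. ~12% expected
    foreground) so early training is not spent un-learning a 50/50 prior —
    the usual initialisation for class-imbalanced dense prediction.
    """

    def __init__(self, in_channels: int, *, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, 1, 1, bias=True, rng=rng)
        self.conv.bias.data[:] = -2.0

    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(self.conv(x))


class SegmentationNet(Module):
    """Encoder-decoder built from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, *, seed: int = 0,
                 lmlp_kwargs: dict | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stage_modules: dict[int, Module] = {}
        for s in spec.stages:
            if s.kind in ("LDA-A", "LDA-B"):
                mod = LDABlock(LdaConfig(s.in_channels, s.out_channels,
                                         stride=s.scale,
                                         use_se=(s.kind == "LDA-B")), rng=rng)
            elif s.kind == "LMLP":
                mod = _EmbeddedLMLP(s.in_channels, s.out_channels, s.scale,
                                    rng=rng, lmlp_kwargs=lmlp_kwargs)
            elif s.kind == "BilinearUp":
                mod = UpsampleBilinear2x()
            elif s.kind == "Head":
                mod = _Head(s.in_channels, rng=rng)
            else:
                raise ValueError(f"unknown stage kind {s.kind!r}")
            setattr(self, f"stage{s.index}", mod)
            self.stage_modules[s.index] = mod
        self.skip_convs: dict[int, Conv2d] = {}
        chan = {s.index: s.out_channels for s in spec.stages}
        for enc_idx, dec_idx in spec.skips.pairs:
            conv = Conv2d(chan[enc_idx], chan[enc_idx], 1, bias=True, rng=rng)
            setattr(self, f"skip{enc_idx}_{dec_idx}", conv)
            self.skip_convs[dec_idx] = conv
        self._skip_sources = {dec: enc for enc, dec in spec.skips.pairs}
        self.skip_gain = 1.0    # scales skip contributions (1 = normal)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        if c != self.spec.stages[0].in_channels:
            raise ValueError(f"expected {self.spec.stages[0].in_channels}-channel "
                             f"input, got {c}")
        if h % 32 or w % 32:
            raise ValueError(f"input size {h}x{w} must be divisible by 32")
        enc_outputs: dict[int, Tensor] = {}
        for s in self.spec.stages:
            x = self.stage_modules[s.index](x)
            if s.index <= 5:
                enc_outputs[s.index] = x
            if s.index in self._skip_sources:
                enc_idx = self._skip_sources[s.index]
                skip = self.skip_convs[s.index](enc_outputs[enc_idx])
                x = x + self.skip_gain * skip
        return x


class _DoubleConv(Module):
    def __init__(self, a: int, b: int, *, rng):
        super().__init__()
        self.net = Sequential(
            Conv2d(a, b, 3, rng=rng), BatchNorm2d(b), ReLU(),
            Conv2d(b, b, 3, rng=rng), BatchNorm2d(b), ReLU())

    def forward(self, x):
        return self.net(x)


class UNetBaseline(Module):
    """Classic 5-level UNet (64..1024 channels, transposed-conv decoder).

    Decoder levels concatenate the skip feature with the upsampled map,
    then apply two 3x3 convolutions; the head is a 1x1 conv + sigmoid.
    """

    def __init__(self, *, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        ch = [64, 128, 256, 512, 1024]
        self.inc = _DoubleConv(3, ch[0], rng=rng)
        self.pool = MaxPool2x2()
        self.down1 = _DoubleConv(ch[0], ch[1], rng=rng)
        self.down2 = _DoubleConv(ch[1], ch[2], rng=rng)
        self.down3 = _DoubleConv(ch[2], ch[3], rng=rng)
        self.down4 = _DoubleConv(ch[3], ch[4], rng=rng)
        self.up1 = ConvTranspose2d(ch[4], ch[3], rng=rng)
        self.dec1 = _DoubleConv(ch[4], ch[3], rng=rng)
        self.up2 = ConvTranspose2d(ch[3], ch[2], rng=rng)
        self.dec2 = _DoubleConv(ch[3], ch[2], rng=rng)
        self.up3 = ConvTranspose2d(ch[2], ch[1], rng=rng)
        self.dec3 = _DoubleConv(ch[2], ch[1], rng=rng)
        self.up4 = ConvTranspose2d(ch[1], ch[0], rng=rng)
        self.dec4 = _DoubleConv(ch[1], ch[0], rng=rng)
        self.head = Conv2d(ch[0], 1, 1, bias=True, rng=rng)
        self.head.bias.data[:] = -2.0    # background-prior logit

    @staticmethod
    def _cat(a: Tensor, b: Tensor) -> Tensor:
        data = np.concatenate([a.data, b.data], axis=1)
        out = Tensor(data, parents=(a, b))
        na = a.shape[1]

        def bw(g):
            a._accumulate(g[:, :na])
            b._accumulate(g[:, na:])
        out._backward = bw
        return out

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input size must be divisible by 32")
        x1 = self.inc(x)
        x2 = self.down1(self.pool(x1))
        x3 = self.down2(self.pool(x2))
        x4 = self.down3(self.pool(x3))
        x5 = self.down4(self.pool(x4))
        y = self.dec1(self._cat(x4, self.up1(x5)))
        y = self.dec2(self._cat(x3, self.up2(y)))
        y = self.dec3(self._cat(x2, self.up3(y)))
        y = self.dec4(self._cat(x1, self.up4(y)))
        return T.sigmoid(self.head(y))

    def fingerprint(self) -> str:
        return "unet-baseline-64-1024-tconv"


def build_lcmunet(*, seed: int = 0, lmlp_kwargs: dict | None = None) -> SegmentationNet:
    """Build the canonical 16-stage model."""
    return SegmentationNet(canonical_spec(), seed=seed, lmlp_kwargs=lmlp_kwargs)


def build_variant(name: str, *, seed: int = 0) -> Module:
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid: {', '.join(VARIANTS)}")
    if name == "unet_baseline":
        return UNetBaseline(seed=seed)
    return SegmentationNet(variant_spec(name), seed=seed)


def model_fingerprint(model: Module) -> str:
    if isinstance(model, SegmentationNet):
        return model.spec.fingerprint()
    return model.fingerprint()


class FingerprintMismatch(RuntimeError):
    pass


def save_checkpoint(model: Module, path, *, variant: str, meta: dict | None = None):
    """Serialise weights plus an architecture fingerprint to one .npz file."""
    state = model.state_dict()
    header = json.dumps({"variant": variant,
                         "fingerprint": model_fingerprint(model),
                         "meta": meta or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path, *, seed: int = 0) -> tuple[Module, dict]:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__header__"}
    model = build_variant(header["variant"], seed=seed)
    if model_fingerprint(model) != header["fingerprint"]:
        raise FingerprintMismatch(
            f"checkpoint fingerprint {header['fingerprint']} does not match "
            f"the built {header['variant']} model")
    model.load_state_dict(state)
    return model, header
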