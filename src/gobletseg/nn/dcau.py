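"""Dual-channel attention U-Net (DCAU-Net) and the standard U-Net baseline.

DCAU-Net keeps the U-Net encoder/decoder skeleton but replaces each encoder
stage with a dual-channel convolution (DCC) block and each skip connection
with a global channel attention (GCA) module:

* the *semantic* channel runs a single 3x3 conv block in parallel with two
  stacked 3x3 conv blocks (5x5 effective receptive field) and sums the two
  paths; each block is residual conv + batch norm + ReLU;
* the *texture* channel runs two asymmetric convolutions (k x 1 then 1 x k,
  default k=7) whose large anisotropic support captures background texture
  and cell boundaries at a fraction of a k x k kernel's parameters;
* the two channels are fused element-wise (I' = semantic + texture); the
  GCA squeezes I' to a per-channel descriptor I_s by global average pooling
  (I_s[c] = mean over the H x W plane), condenses the channel depth to a
  single-channel attention map I_A with a pointwise 1x1 convolution, and
  forms the refined map I_R = sigmoid(I_A) * I_s — the outer product of a
  (C,1,1) descriptor and a (1,H,W) gate. I_R multiplies I' and the product
  is what the skip connection hands to the decoder.

The decoder mirrors the encoder with bilinear x2 upsampling, concatenation
of the GCA skip output, and 3x3 conv blocks, ending in a 1-channel sigmoid
probability map at input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat_channels
from .layers import (BatchNorm2d, Conv2d, ConvBlock, MaxPool2x2, Module,
                     Sequential, UpsampleBilinear2x, ConvTranspose2x2)

__all__ = ["ModelConfig", "SemanticChannel", "TextureChannel", "GCA",
           "DCAUNet", "UNet", "build_dcau_net", "build_unet_baseline",
           "semantic_channel", "texture_channel", "gca"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``depth`` encoder stages with widths ``base_channels * 2**s``;
    ``texture_kernel_len`` is the asymmetric kernel length k (odd, >= 3).
    ``gate_prefusion`` switches the GCA multiplication from the fused map
    I' (default) to the raw semantic-channel features.
    """

    depth: int = 4
    base_channels: int = 64
    texture_kernel_len: int = 7
    use_residual: bool = True
    gate_prefusion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        k = self.texture_kernel_len
        if k < 3 or k % 2 == 0:
            raise ValueError("texture_kernel_len must be odd and >= 3")

    def stage_width(self, s: int) -> int:
        return self.base_channels * 2**s


class SemanticChannel(Module):
    """Multi-scale 3x3 path: single block + two stacked blocks, summed."""

    def __init__(self, cin: int, cout: int, residual: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.single = ConvBlock(cin, cout, 3, residual, rng=rng)
        self.stacked = Sequential(ConvBlock(cin, cout, 3, residual, rng=rng),
                                  ConvBlock(cout, cout, 3, residual, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        return self.single(x) + self.stacked(x)


class TextureChannel(Module):
    """Two asymmetric conv layers (k x 1 then 1 x k), stride 1, same padding."""

    def __init__(self, cin: int, cout: int, k: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.a = Sequential(Conv2d(cin, cout, (k, 1), rng=rng),
                            BatchNorm2d(cout))
        self.b = Sequential(Conv2d(cout, cout, (1, k), rng=rng),
                            BatchNorm2d(cout))

    def forward(self, x: Tensor) -> Tensor:
        return self.b(self.a(x).relu()).relu()


class GCA(Module):
    """Global channel attention over the fused DCC output.

    Returns ``I_R * target`` where ``I_R = sigmoid(conv1x1(I')) * I_s`` and
    ``I_s`` is the per-channel global average of ``I'``.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.squeeze = Conv2d(channels, 1, 1, rng=rng)

    def forward(self, fused: Tensor, target: Tensor | None = None) -> Tensor:
        i_s = fused.spatial_mean()                 # (N,C,1,1)
        i_a = self.squeeze(fused)                  # (N,1,H,W)
        i_r = i_a.sigmoid() * i_s                  # outer product -> (N,C,H,W)
        return i_r * (fused if target is None else target)


class _DCCStage(Module):
    def __init__(self, cin: int, cout: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.semantic = SemanticChannel(cin, cout, cfg.use_residual, rng)
        self.texture = TextureChannel(cin, cout, cfg.texture_kernel_len, rng)
        self.gca = GCA(cout, rng)
        self.gate_prefusion = cfg.gate_prefusion

    def forward(self, x: Tensor):
        sem = self.semantic(x)
        tex = self.texture(x)
        fused = sem + tex
        skip = self.gca(fused, sem if self.gate_prefusion else None)
        return fused, skip


class _DecoderStage(Module):
    def __init__(self, cin: int, cskip: int, cout: int,
                 rng: np.random.Generator):
        super().__init__()
        self.up = UpsampleBilinear2x()
        self.reduce = Conv2d(cin, cout, 1, rng=rng)
        self.block1 = ConvBlock(cout + cskip, cout, 3, rng=rng)
        self.block2 = ConvBlock(cout, cout, 3, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.reduce(self.up(x))
        x = concat_channels([x, skip])
        return self.block2(self.block1(x))


class DCAUNet(Module):
    """Encoder of DCC stages with GCA skips, mirrored bilinear-up decoder."""

    def __init__(self, cfg: ModelConfig, in_channels: int = 1):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.pool = MaxPool2x2()
        cin = in_channels
        self.enc_stages: list[_DCCStage] = []
        for s in range(cfg.depth):
            w = cfg.stage_width(s)
            stage = _DCCStage(cin, w, cfg, rng)
            self._modules[f"enc{s}"] = stage
            self.enc_stages.append(stage)
            cin = w
        wb = cfg.stage_width(cfg.depth)
        self.bottleneck = Sequential(ConvBlock(cin, wb, 3, rng=rng),
                                     ConvBlock(wb, wb, 3, rng=rng))
        self.dec_stages: list[_DecoderStage] = []
        cin = wb
        for s in reversed(range(cfg.depth)):
            w = cfg.stage_width(s)
            stage = _DecoderStage(cin, w, w, rng)
            self._modules[f"dec{s}"] = stage
            self.dec_stages.append(stage)
            cin = w
        self.head = Conv2d(cin, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        self._check_divisible(x)
        skips = []
        for stage in self.enc_stages:
            fused, skip = stage(x)
            skips.append(skip)
            x = self.pool(fused)
        x = self.bottleneck(x)
        for stage, skip in zip(self.dec_stages, reversed(skips)):
            x = stage(x, skip)
        return self.head(x).sigmoid()

    def _check_divisible(self, x: Tensor) -> None:
        h, w = x.shape[-2:]
        d = 2**self.cfg.depth
        if h % d or w % d:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {d}; "
                "pad or crop the tile first"
            )


class _UNetDouble(Module):
    """Two 3x3 conv + ReLU layers (classic U-Net block, no BN)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = Conv2d(cin, cout, 3, rng=rng)
        self.c2 = Conv2d(cout, cout, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x).relu()).relu()


class UNet(Module):
    """Standard U-Net with same-padding convolutions and sigmoid output.

    Classic widths (64..1024 with depth 4) give about 31M parameters.
    """

    def __init__(self, cfg: ModelConfig, in_channels: int = 1):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.pool = MaxPool2x2()
        cin = in_channels
        self.enc: list[_UNetDouble] = []
        for s in range(cfg.depth):
            w = cfg.stage_width(s)
            blk = _UNetDouble(cin, w, rng)
            self._modules[f"enc{s}"] = blk
            self.enc.append(blk)
            cin = w
        wb = cfg.stage_width(cfg.depth)
        self.bottleneck = _UNetDouble(cin, wb, rng)
        self.ups: list[ConvTranspose2x2] = []
        self.dec: list[_UNetDouble] = []
        cin = wb
        for s in reversed(range(cfg.depth)):
            w = cfg.stage_width(s)
            up = ConvTranspose2x2(cin, w, rng)
            blk = _UNetDouble(2 * w, w, rng)
            self._modules[f"up{s}"] = up
            self._modules[f"dec{s}"] = blk
            self.ups.append(up)
            self.dec.append(blk)
            cin = w
        self.head = Conv2d(cin, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[-2:]
        d = 2**self.cfg.depth
        if h % d or w % d:
            raise ValueError(f"input {h}x{w} not divisible by 2^depth = {d}")
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = concat_channels([up(x), skip])
            x = blk(x)
        return self.head(x).sigmoid()


def build_dcau_net(config: ModelConfig | None = None, in_channels: int = 1) -> DCAUNet:
    return DCAUNet(config or ModelConfig(), in_channels)


def build_unet_baseline(config: ModelConfig | None = None, in_channels: int = 1) -> UNet:
    return UNet(config or ModelConfig(), in_channels)


# ---- functional surface (single-tensor convenience wrappers) -------------

def semantic_channel(x: Tensor | np.ndarray, cout: int,
                     seed: int = 0) -> Tensor:
    """Apply a freshly initialized semantic channel to one C x H x W map."""
    x = _as_batched(x)
    mod = SemanticChannel(x.shape[1], cout, rng=np.random.default_rng(seed))
    mod.eval()
    return mod(x)


def texture_channel(x: Tensor | np.ndarray, cout: int, k: int = 7,
                    seed: int = 0) -> Tensor:
    x = _as_batched(x)
    mod = TextureChannel(x.shape[1], cout, k, rng=np.random.default_rng(seed))
    mod.eval()
    return mod(x)


def gca(semantic: Tensor | np.ndarray, texture: Tensor | np.ndarray,
        seed: int = 0, weights: np.ndarray | None = None,
        bias: float | None = None) -> Tensor:
    """Fuse semantic+texture maps and apply global channel attention.

    ``weights``/``bias`` optionally pin the 1x1 squeeze convolution (e.g.
    zeros, for the analytic sigmoid(0) = 0.5 reduction).
    """
    s, t = _as_batched(semantic), _as_batched(texture)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {t.shape}")
    mod = GCA(s.shape[1], rng=np.random.default_rng(seed))
    if weights is not None:
        mod.squeeze.w.data[...] = np.asarray(weights).reshape(mod.squeeze.w.shape)
    if bias is not None:
        mod.squeeze.b.data[...] = bias
    mod.eval()
    return mod(s + t)


def _as_batched(x) -> Tensor:
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.data.ndim == 3:
        x = x.reshape(1, *x.data.shape)
    if x.data.ndim != 4:
        raise ValueError("expected C x H x W or N x C x H x W input")
    return x
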