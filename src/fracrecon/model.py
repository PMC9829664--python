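"""Biplanar 2D→3D reconstruction network.

Architecture: per-view dense-block encoders extract an L-level 2D feature
pyramid from each radiograph; per-view decoders turn each level into a
cubical 3D feature block by reshaping channels into the depth dimension;
a fusion path aligns the second view to the first with a 90° permutation
about the vertical axis and merges the two pyramids coarse-to-fine:

    F(i) = Θ3D([D1(i), P(D2(i)), U3D(F(i+1))])   for i < L-1
    F(L-1) = Θ3D([D1(L-1), P(D2(L-1))])

with Θ3D a stack of 3×3×3 convolutions (instance norm + ReLU) and U3D a
kernel-2 stride-2 transposed convolution.  A final 1×1×1 convolution
produces per-voxel class scores; softmax yields class probabilities.

Feature layout convention: 3D blocks are (N, C, depth, height, width) with
height the vertical (z) axis; the permutation P rotates the two horizontal
axes (depth, width) by 90°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Conv, ConvTranspose, InstanceNorm, Module, Tensor


@dataclass
class NetworkConfig:
    """Depth/width configuration of the reconstruction network.

    ``levels`` is the number of pyramid levels L; the input image extent
    must be a power-of-two multiple of 2^(L-1).  ``channels_3d`` is the 3D
    channel count after the channels→depth reshape, so each 2D decoded
    level carries ``extent(i) * channels_3d`` channels.
    """

    levels: int = 7
    image_size: int = 128
    n_classes: int = 3
    base_channels: int = 8
    growth: int = 4
    dense_layers: int = 4
    channels_3d: int = 4
    up_channels: int = 8
    fusion_channels: int = 8
    fusion_convs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 pyramid levels")
        if self.n_classes not in (2, 3):
            raise ValueError("output classes must be 2 or 3")
        stride = 2 ** (self.levels - 1)
        if self.image_size < stride or self.image_size % stride:
            raise ValueError(
                f"image size {self.image_size} must be a multiple of "
                f"2^(L-1) = {stride}"
            )

    def extent(self, level: int) -> int:
        return self.image_size // 2**level

    def encoder_channels(self) -> list[int]:
        """Output channels of each encoder level's dense block."""
        out = []
        c = self.base_channels
        for _ in range(self.levels):
            c = c + self.dense_layers * self.growth
            out.append(c)
        return out

    def decoder_channels(self) -> list[int]:
        """2D decoded channels per level: extent(i) * channels_3d."""
        return [self.extent(i) * self.channels_3d for i in range(self.levels)]


class DenseLayer(Module):
    """IN → ReLU → 3×3 conv emitting ``growth`` channels."""

    def __init__(self, rng, c_in: int, growth: int):
        self.norm = InstanceNorm(c_in)
        self.conv = Conv(rng, c_in, growth, 3, nd=2)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(ad.relu(self.norm(x)))


class DenseBlock(Module):
    """Densely connected block: each layer sees all previous outputs."""

    def __init__(self, rng, c_in: int, growth: int, n_layers: int):
        self.layers = [
            DenseLayer(rng, c_in + j * growth, growth) for j in range(n_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        feats = x
        for layer in self.layers:
            feats = ad.concat([feats, layer(feats)], axis=1)
        return feats


class Encoder(Module):
    """Per-view 2D encoder: stem conv, then L dense-block levels with 2× max-pooling."""

    def __init__(self, rng, cfg: NetworkConfig):
        self.stem = Conv(rng, 1, cfg.base_channels, 3, nd=2)
        self.blocks = []
        c = cfg.base_channels
        for _ in range(cfg.levels):
            self.blocks.append(DenseBlock(rng, c, cfg.growth, cfg.dense_layers))
            c = c + cfg.dense_layers * cfg.growth

    def __call__(self, x: Tensor) -> list[Tensor]:
        feats = self.stem(x)
        pyramid = []
        for i, block in enumerate(self.blocks):
            feats = block(feats)
            pyramid.append(feats)
            if i < len(self.blocks) - 1:
                feats = ad.maxpool2d(feats)
        return pyramid


class Decoder(Module):
    """Per-view top-down 2D decoder producing cubical 3D blocks per level.

    At each level the (upsampled previous decode, same-scale encode) are
    concatenated and convolved to ``extent(i) * channels_3d`` channels, so
    the channels→depth reshape yields a (C3D, extent, extent, extent) block.
    """

    def __init__(self, rng, cfg: NetworkConfig):
        self.cfg = cfg
        enc_c = cfg.encoder_channels()
        dec_c = cfg.decoder_channels()
        self.convs = []
        self.norms = []
        self.ups = []
        for i in range(cfg.levels):
            c_in = enc_c[i] if i == cfg.levels - 1 else enc_c[i] + cfg.up_channels
            self.convs.append(Conv(rng, c_in, dec_c[i], 3, nd=2))
            self.norms.append(InstanceNorm(dec_c[i]))
        for i in range(1, cfg.levels):
            self.ups.append(ConvTranspose(rng, dec_c[i], cfg.up_channels, nd=2))

    def __call__(self, pyramid: list[Tensor]) -> list[Tensor]:
        cfg = self.cfg
        blocks: list[Tensor | None] = [None] * cfg.levels
        prev = None
        for i in range(cfg.levels - 1, -1, -1):
            if i == cfg.levels - 1:
                x = pyramid[i]
            else:
                x = ad.concat([self.ups[i](prev), pyramid[i]], axis=1)
            d = ad.relu(self.norms[i](self.convs[i](x)))
            blocks[i] = reshape_channels_to_depth(d, cfg.channels_3d)
            prev = d
        return blocks  # type: ignore[return-value]


def reshape_channels_to_depth(d: Tensor, channels_3d: int) -> Tensor:
    """(N, extent*C3D, H, W) → (N, C3D, extent, H, W); exact inverse exists."""
    n, c, h, w = d.shape
    if c % channels_3d:
        raise ValueError(f"{c} channels do not factor into {channels_3d} 3D channels")
    return ad.reshape(d, (n, channels_3d, c // channels_3d, h, w))


def reshape_depth_to_channels(block: Tensor) -> Tensor:
    """Inverse of :func:`reshape_channels_to_depth`."""
    n, c3, depth, h, w = block.shape
    return ad.reshape(block, (n, c3 * depth, h, w))


def permute_view2(block: Tensor) -> Tensor:
    """Rotate a cubical feature block 90° about the vertical axis.

    Aligns the second view's frame to the first: swap the two horizontal
    spatial axes (depth ↔ width) then flip the new depth axis.  Applying it
    four times is the identity.
    """
    if block.data.ndim != 5:
        raise ValueError("expected (N, C, D, H, W) features")
    n, c, d, h, w = block.shape
    if d != w:
        raise ValueError("permutation requires depth == width (cubical block)")
    return ad.flip(ad.transpose(block, (0, 1, 4, 3, 2)), axis=2)


class FusionLevel(Module):
    """Θ3D at one level: ``fusion_convs`` × (3×3×3 conv → IN → ReLU)."""

    def __init__(self, rng, c_in: int, c_out: int, n_convs: int):
        self.convs = []
        self.norms = []
        c = c_in
        for _ in range(n_convs):
            self.convs.append(Conv(rng, c, c_out, 3, nd=3))
            self.norms.append(InstanceNorm(c_out))
            c = c_out

    def __call__(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = ad.relu(norm(conv(x)))
        return x


class Fusion(Module):
    """Coarse-to-fine fusion of the two view pyramids with upsampling."""

    def __init__(self, rng, cfg: NetworkConfig):
        self.cfg = cfg
        fc = cfg.fusion_channels
        self.levels = []
        for i in range(cfg.levels):
            c_in = 2 * cfg.channels_3d + (fc if i < cfg.levels - 1 else 0)
            self.levels.append(FusionLevel(rng, c_in, fc, cfg.fusion_convs))
        self.ups = [ConvTranspose(rng, fc, fc, nd=3) for _ in range(cfg.levels - 1)]
        self.up_norms = [InstanceNorm(fc) for _ in range(cfg.levels - 1)]
        self.classifier = Conv(rng, fc, cfg.n_classes, 1, nd=3)

    def __call__(self, d1: list[Tensor], d2: list[Tensor]) -> Tensor:
        cfg = self.cfg
        fused = None
        for i in range(cfg.levels - 1, -1, -1):
            parts = [d1[i], permute_view2(d2[i])]
            if i < cfg.levels - 1:
                up = ad.relu(self.up_norms[i](self.ups[i](fused)))
                parts.append(up)
            fused = self.levels[i](ad.concat(parts, axis=1))
        return self.classifier(fused)


class ReconNet3D(Module):
    """Full biplanar reconstruction network (two encoders/decoders + fusion)."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder1 = Encoder(rng, cfg)
        self.encoder2 = Encoder(rng, cfg)
        self.decoder1 = Decoder(rng, cfg)
        self.decoder2 = Decoder(rng, cfg)
        self.fusion = Fusion(rng, cfg)

    def forward(self, x: Tensor, return_pyramids: bool = False):
        """x (N, 2, H, W) → per-voxel class scores (N, C, D, H, W)."""
        if x.data.ndim != 4 or x.shape[1] != 2:
            raise ValueError(f"expected input (N, 2, H, W), got {x.shape}")
        if x.shape[2] != self.cfg.image_size or x.shape[3] != self.cfg.image_size:
            raise ValueError(
                f"input extent {x.shape[2:]} does not match configured "
                f"image size {self.cfg.image_size}"
            )
        x1 = ad.narrow(x, 0, 1, axis=1)
        x2 = ad.narrow(x, 1, 1, axis=1)
        e1 = self.encoder1(x1)
        e2 = self.encoder2(x2)
        d1 = self.decoder1(e1)
        d2 = self.decoder2(e2)
        logits = self.fusion(d1, d2)
        if return_pyramids:
            return logits, {"e1": e1, "e2": e2, "D1": d1, "D2": d2}
        return logits

    __call__ = forward


def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Softmax over the class axis of (N, C, ...) scores."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# world-volume ↔ network-layout converters
# ---------------------------------------------------------------------------

def volume_to_target(data: np.ndarray) -> np.ndarray:
    """(x, y, z)-indexed volume → network (depth=y, height=z, width=x)."""
    return np.ascontiguousarray(np.transpose(data, (1, 2, 0)))


def target_to_volume(data: np.ndarray) -> np.ndarray:
    """Inverse of :func:`volume_to_target`."""
    return np.ascontiguousarray(np.transpose(data, (2, 0, 1)))
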