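"""3D residual feature extractor for single-channel volumes.

The network consists of four stacked residual modules and nothing else: no
stem pooling before the first block (the input volume enters the residual
stack directly) and no global pooling after the last one — the classifier
head consumes the full spatial feature map, which is the point of the
reconstruction-based approach.  Each residual module is two 3D conv + batch
norm + rectifier layers with an identity skip (1×1×1-projected when channels
or resolution change).

A volume of shape (D, H, W) is mapped to a FeatureMap: an r×d matrix holding
the d-channel feature vector at each of the r surviving spatial locations,
flattened row-major over (depth, height, width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, no_grad

__all__ = [
    "BackboneConfig",
    "FeatureMap",
    "conv3d_output_shape",
    "build_backbone",
    "extract_feature_map",
    "feature_map_shape",
    "receptive_field_range",
    "Backbone",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the four-block residual extractor.

    The defaults (16, 32, 64, 128) with stride-2 down-sampling in blocks 2-4
    map a 64³ input to an 8³×128 feature map (r=512, d=128) — small enough
    for CPU work while keeping a non-trivial spatial grid for the
    reconstruction head.
    """

    in_channels: int = 1
    block_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel_size: int = 3
    downsample_per_block: tuple[bool, bool, bool, bool] = (False, True, True, True)

    def __post_init__(self):
        if len(self.block_channels) != 4 or len(self.downsample_per_block) != 4:
            raise ValueError("exactly four residual blocks are required")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.in_channels < 1 or any(c < 1 for c in self.block_channels):
            raise ValueError("channel counts must be positive")

    @property
    def feature_channels(self) -> int:
        return self.block_channels[-1]


@dataclass
class FeatureMap:
    """r×d matrix of d-channel feature vectors at r spatial locations."""

    values: np.ndarray
    spatial_shape: tuple[int, int, int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        r = int(np.prod(self.spatial_shape))
        if self.values.ndim != 2 or self.values.shape[0] != r:
            raise ValueError(
                f"values must be r×d with r={r}, got shape {self.values.shape}"
            )
        if r < 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("feature map must be non-empty and finite")

    @property
    def r(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def conv3d_output_shape(h: int, w: int, d: int, k: int, n: int) -> tuple[int, int, int, int]:
    """Output size of a valid (unpadded, stride-1) k×k×k convolution with n
    filters on an h×w×d input: (h−k+1, w−k+1, d−k+1, n)."""
    if k < 1:
        raise ValueError("kernel size must be >= 1")
    if min(h, w, d) < k:
        raise ValueError(f"kernel {k} larger than input ({h},{w},{d})")
    return (h - k + 1, w - k + 1, d - k + 1, n)


def _block_spatial(size: int, k: int, stride: int) -> int:
    """One padded conv layer's output length along one axis.

    With shape-preserving padding p=k//2 the stride-s output equals the valid
    conv length of the padded input subsampled every s: ceil((n+2p−k+1)/s).
    """
    p = k // 2
    full = conv3d_output_shape(size + 2 * p, size + 2 * p, size + 2 * p, k, 1)[0]
    return -(-full // stride)


def feature_map_shape(cfg: BackboneConfig, input_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Spatial shape of the feature map for a given input, by composing the
    per-layer convolution arithmetic over the four blocks."""
    shape = tuple(input_shape)
    for down in cfg.downsample_per_block:
        s = 2 if down else 1
        shape = tuple(_block_spatial(n, cfg.kernel_size, s) for n in shape)  # conv 1
        shape = tuple(_block_spatial(n, cfg.kernel_size, 1) for n in shape)  # conv 2
    return shape


class _ResidualBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, *, rng):
        super().__init__()
        p = k // 2
        self.conv1 = nn.Conv3d(in_ch, out_ch, k, stride=stride, padding=p, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm3d(out_ch)
        self.conv2 = nn.Conv3d(out_ch, out_ch, k, stride=1, padding=p, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm3d(out_ch)
        if in_ch != out_ch or stride != 1:
            self.proj = nn.Conv3d(in_ch, out_ch, 1, stride=stride, padding=0, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm3d(out_ch)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = x if self.proj is None else self.proj_bn(self.proj(x))
        return (out + skip).relu()


class Backbone(nn.Module):
    """Four residual modules; input (N, C_in, D, H, W) → features (N, d, ...)."""

    def __init__(self, cfg: BackboneConfig, seed: int):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        blocks = []
        in_ch = cfg.in_channels
        for out_ch, down in zip(cfg.block_channels, cfg.downsample_per_block):
            blocks.append(_ResidualBlock(in_ch, out_ch, cfg.kernel_size,
                                         2 if down else 1, rng=rng))
            in_ch = out_ch
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


def build_backbone(cfg: BackboneConfig, seed: int) -> Backbone:
    """Construct the extractor with deterministic (seeded) initialisation."""
    return Backbone(cfg, seed)


def extract_feature_map(backbone: Backbone, volume: np.ndarray) -> FeatureMap:
    """Run one volume through the frozen extractor (evaluation mode).

    The (d-channel) output grid is flattened row-major over
    (depth, height, width) into the r×d matrix.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape}")
    was_training = backbone.training
    backbone.eval()
    try:
        with no_grad():
            out = backbone(Tensor(vol[None, None]))
    finally:
        backbone.train(was_training)
    return _to_feature_maps(out)[0]


def _to_feature_maps(out: Tensor) -> list[FeatureMap]:
    """Convert a batched (N, d, D', H', W') activation tensor to FeatureMaps."""
    data = out.data
    n, d = data.shape[0], data.shape[1]
    spatial = tuple(int(s) for s in data.shape[2:])
    flat = data.transpose(0, 2, 3, 4, 1).reshape(n, -1, d)
    return [FeatureMap(values=flat[i], spatial_shape=spatial) for i in range(n)]


def receptive_field_range(cfg: BackboneConfig, out_index: tuple[int, int, int],
                          input_shape: tuple[int, int, int]) -> list[tuple[int, int]]:
    """Inclusive per-axis input index range that can influence one output
    location, obtained by mapping the index interval backward through every
    conv layer (the 1×1×1 projection never widens it)."""
    layers = []
    k, p = cfg.kernel_size, cfg.kernel_size // 2
    for down in cfg.downsample_per_block:
        layers.append((k, 2 if down else 1, p))
        layers.append((k, 1, p))
    ranges = [(int(i), int(i)) for i in out_index]
    for kk, s, pp in reversed(layers):
        ranges = [(lo * s - pp, hi * s - pp + kk - 1) for lo, hi in ranges]
    return [(max(lo, 0), min(hi, n - 1)) for (lo, hi), n in zip(ranges, input_shape)]
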