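"""Generator and discriminator architectures for z-sweep -> z-projection restoration.

Two generators are provided, both single-channel image-to-image U-Nets:

* ``standard`` — the classic encoder/decoder with two [3x3 conv, batch norm,
  ReLU] units per level, max-pool downsampling and bilinear upsampling with
  skip concatenations.
* ``osa`` — the same skeleton with each level's second unit replaced by a
  one-shot-aggregation (OSA) block: a chain of 3x3 convolutions whose input
  and every intermediate output are concatenated once, projected back to the
  input width by a 1x1 convolution, re-weighted per channel by an efficient
  squeeze-and-excitation (eSE) gate, and added back to the block input.

The adversarial critic is a PatchGAN: a strided convolutional ladder that
emits a grid of per-patch real/fake probabilities rather than a single
scalar, with a 70 px receptive field per output unit in its default
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "OSABlock", "UNet", "PatchGAN",
    "build_generator", "build_discriminator", "receptive_field",
    "empirical_receptive_field", "discriminator_output_shape", "count_parameters",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Hyperparameters of the restoration generator G.

    ``depth`` counts down/upsampling levels; input spatial dims must be
    divisible by ``2**depth``.  ``osa_layers`` is the number of chained 3x3
    convolutions inside each OSA block (ignored for ``standard`` blocks).
    """

    block_type: str = "standard"
    depth: int = 4
    base_channels: int = 64
    osa_layers: int = 3
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.block_type not in ("standard", "osa"):
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.depth < 1 or self.base_channels < 1 or self.osa_layers < 1:
            raise ValueError("depth, base_channels and osa_layers must be >= 1")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN hyperparameters.

    The stride pattern [2, 2, 2, 1, 1] with 4x4 kernels and padding 1 yields
    the 70 px receptive field of the pix2pix patch critic; the final sigmoid
    maps each patch logit to a probability in [0, 1].
    """

    kernel: int = 4
    strides: Tuple[int, ...] = (2, 2, 2, 1, 1)
    channels: Tuple[int, ...] = (64, 128, 256, 512, 1)
    leaky_slope: float = 0.2
    in_channels: int = 2
    padding: int = 1

    def __post_init__(self):
        if len(self.strides) != len(self.channels):
            raise ValueError("strides and channels must have equal length")
        if len(self.strides) == 0:
            raise ValueError("discriminator needs at least one layer")


class _StandardUnit(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class OSABlock(nn.Module):
    """One-shot aggregation block with an eSE gate; preserves channel count.

    y = x + eSE(F_1x1([x, h_1, ..., h_L]))  with  h_i = ReLU(F_3x3(h_{i-1})),
    where the eSE gate multiplies each channel of the projected tensor by
    hard_sigmoid(F_1x1(avg_pool(.))), broadcast over the spatial dimensions.
    """

    def __init__(self, channels: int, osa_layers: int, rng: np.random.Generator):
        super().__init__()
        self.convs = [nn.Conv2d(channels, channels, 3, padding=1, rng=rng)
                      for _ in range(osa_layers)]
        self.project = nn.Conv2d(channels * (osa_layers + 1), channels, 1, rng=rng)
        self.ese = nn.Conv2d(channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        h = x
        for conv in self.convs:
            h = conv(h).relu()
            feats.append(h)
        projected = self.project(nn.concat(feats, axis=1))
        gate = self.ese(nn.global_avg_pool(projected)).hard_sigmoid()
        return projected * gate + x


class _Level(nn.Module):
    """One resolution level of the U-Net: channel adaptation + feature unit."""

    def __init__(self, spec: GeneratorSpec, in_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.first = _StandardUnit(in_ch, out_ch, rng)
        if spec.block_type == "osa":
            self.second: nn.Module = OSABlock(out_ch, spec.osa_layers, rng)
        else:
            self.second = _StandardUnit(out_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.second(self.first(x))


class UNet(nn.Module):
    """Encoder/decoder generator with skip concatenations.

    Downsampling is 2x2 max pooling, upsampling bilinear interpolation; the
    head is a linear 1x1 convolution, so outputs are unbounded (images are
    mapped in the log domain during training).
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        chans = [spec.base_channels * 2**i for i in range(spec.depth + 1)]
        self.encoder = [
            _Level(spec, spec.in_channels if i == 0 else chans[i - 1], chans[i], rng)
            for i in range(spec.depth)
        ]
        self.bottleneck = _Level(spec, chans[spec.depth - 1], chans[spec.depth], rng)
        self.decoder = [
            _Level(spec, chans[i + 1] + chans[i], chans[i], rng)
            for i in reversed(range(spec.depth))
        ]
        self.head = nn.Conv2d(chans[0], spec.out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.as_tensor(x)
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        h, w = x.shape[2], x.shape[3]
        div = 2**self.spec.depth
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by 2^depth = {div}")
        skips = []
        for level in self.encoder:
            x = level(x)
            skips.append(x)
            x = nn.max_pool2d(x)
        x = self.bottleneck(x)
        for level, skip in zip(self.decoder, reversed(skips)):
            x = nn.upsample_bilinear2x(x)
            x = level(nn.concat([x, skip], axis=1))
        return self.head(x)


class PatchGAN(nn.Module):
    """Patch discriminator D(S, P) -> [0, 1]^(h_hat x w_hat).

    The two images are stacked into a 2-channel input.  Following the pix2pix
    convention, batch norm is omitted from the first and final layers.
    """

    def __init__(self, spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        n = len(spec.strides)
        self.convs = []
        self.norms = []
        in_ch = spec.in_channels
        for i, (stride, out_ch) in enumerate(zip(spec.strides, spec.channels)):
            self.convs.append(nn.Conv2d(in_ch, out_ch, spec.kernel, stride=stride,
                                        padding=spec.padding, rng=rng))
            use_norm = 0 < i < n - 1
            self.norms.append(nn.BatchNorm2d(out_ch) if use_norm else nn.Module())
            in_ch = out_ch

    def forward(self, sweep: Tensor, projection: Tensor) -> Tensor:
        sweep = nn.as_tensor(sweep)
        projection = nn.as_tensor(projection)
        if sweep.shape != projection.shape:
            raise ValueError("discriminator inputs must share shape")
        x = nn.concat([sweep, projection], axis=1)
        n = len(self.convs)
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            x = conv(x)
            if isinstance(norm, nn.BatchNorm2d):
                x = norm(x)
            if i < n - 1:
                x = x.leaky_relu(self.spec.leaky_slope)
        return x.sigmoid()


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNet:
    return UNet(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(),
                        seed: int = 0) -> PatchGAN:
    return PatchGAN(spec, seed=seed)


def discriminator_output_shape(spec: DiscriminatorSpec, h: int, w: int) -> Tuple[int, int]:
    """Spatial output shape of the patch grid for an h x w input."""
    for s in spec.strides:
        h = (h + 2 * spec.padding - spec.kernel) // s + 1
        w = (w + 2 * spec.padding - spec.kernel) // s + 1
    return h, w


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Side length (pixels) of one output unit's receptive field.

    Backward recurrence RF <- (RF - 1) * stride + kernel, starting from a
    single output unit and walking the layers output-to-input.
    """
    if len(spec.strides) == 0:
        raise ValueError("empty layer list")
    rf = 1
    for s in reversed(spec.strides):
        rf = (rf - 1) * s + spec.kernel
    return rf


def empirical_receptive_field(spec: DiscriminatorSpec = DiscriminatorSpec(),
                              input_size: int = 256, seed: int = 0) -> int:
    """Receptive field measured as the nonzero input-gradient footprint.

    Builds the discriminator with random weights (inference mode, so batch
    statistics do not couple distant pixels), backpropagates from a single
    central output unit and returns the side length of the bounding box of
    nonzero input gradient.
    """
    disc = PatchGAN(spec, seed=seed).eval()
    a = Tensor(np.random.default_rng(seed).normal(size=(1, 1, input_size, input_size)),
               requires_grad=True)
    b = Tensor(np.zeros((1, 1, input_size, input_size)))
    out = disc(a, b)
    oh, ow = out.shape[2], out.shape[3]
    g = np.zeros(out.shape)
    g[0, 0, oh // 2, ow // 2] = 1.0
    out.backward(g)
    rows = np.nonzero(np.abs(a.grad[0, 0]).sum(axis=1))[0]
    cols = np.nonzero(np.abs(a.grad[0, 0]).sum(axis=0))[0]
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))


def count_parameters(module: nn.Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))
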