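"""Network building blocks: convolutions, normalization, attention, U-Net.

The generator is a residual U-Net with a convolutional block attention
module (CBAM) after each down-sampling stage and before each up-sampling
stage, mapping a single-channel diffuse reflectance image to a three-channel
coefficient label image in [0, 1].  The discriminator is a three-layer fully
convolutional classifier over the channel-concatenated (input, candidate
label) pair, emitting a patch grid of probabilities.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "ResidualBlock",
    "GeneratorConfig",
    "DiscriminatorConfig",
    "build_generator",
    "build_discriminator",
    "assemble_pair",
    "split_pair",
]


class Module:
    """Base class: parameter discovery via attribute walk."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Convolution with He-style normal initialization."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None,
                 bias=True, init_scale=None):
        rng = rng or np.random.default_rng(0)
        scale = init_scale if init_scale is not None else np.sqrt(
            2.0 / (in_ch * kernel * kernel)
        )
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learnable affine."""

    def __init__(self, channels, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        norm = centered / (var + self.eps).sqrt()
        return norm * self.gamma + self.beta


class ChannelAttention(Module):
    """Channel gate: sigmoid(MLP(avgpool) + MLP(maxpool)), shared MLP.

    The reduction ratio is clipped so the hidden width is at least one
    channel.
    """

    #: initial gate-logit bias; starts the attention gates nearly open so the
    #: untrained network does not attenuate the signal path
    OPEN_GATE_BIAS = 2.0

    def __init__(self, channels, reduction=16, rng=None):
        hidden = max(channels // min(reduction, channels), 1)
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)
        self.fc2.bias.data += self.OPEN_GATE_BIAS / 2.0  # two pooling paths sum

    def _mlp(self, pooled: Tensor) -> Tensor:
        return self.fc2(self.fc1(pooled).relu())

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3), keepdims=True)
        mx = x.amax(axis=(2, 3), keepdims=True)
        return (self._mlp(avg) + self._mlp(mx)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


class SpatialAttention(Module):
    """Spatial gate: sigmoid of a kxk conv over channel-mean and channel-max."""

    def __init__(self, kernel=7, rng=None):
        self.conv = Conv2d(2, 1, kernel, padding=kernel // 2, rng=rng)
        self.conv.bias.data += ChannelAttention.OPEN_GATE_BIAS

    def weights(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.amax(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.weights(x)


class CBAM(Module):
    """Sequential channel-then-spatial attention block."""

    def __init__(self, channels, reduction=16, spatial_kernel=7, rng=None):
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


class ResidualBlock(Module):
    """Two 3x3 convs with an identity shortcut.

    No normalization: the absolute intensity level of the reflectance input
    carries the coefficient information, and per-sample normalization would
    erase it on the near-uniform scenes this network is trained on.
    """

    def __init__(self, channels, rng=None):
        self.conv1 = Conv2d(channels, channels, 3, padding=1, rng=rng)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h)
        return (x + h).relu()


class GeneratorConfig:
    """Architecture knobs of the residual attention U-Net."""

    def __init__(self, depth=4, base_channels=16, residual_blocks=1,
                 cbam_reduction_ratio=16, cbam_spatial_kernel=7,
                 in_channels=1, out_channels=3):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        self.base_channels = base_channels
        self.residual_blocks = residual_blocks
        self.cbam_reduction_ratio = cbam_reduction_ratio
        self.cbam_spatial_kernel = cbam_spatial_kernel
        self.in_channels = in_channels
        self.out_channels = out_channels


class DiscriminatorConfig:
    """Three-layer patch classifier over (input, label) channel pairs."""

    def __init__(self, in_channels=4, channels=(16, 32)):
        self.in_channels = in_channels
        self.channels = tuple(channels)


class _DownStage(Module):
    def __init__(self, in_ch, out_ch, n_res, reduction, spatial_kernel, rng):
        self.pre = Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.res = [ResidualBlock(out_ch, rng=rng) for _ in range(n_res)]
        self.down = Conv2d(out_ch, out_ch, 3, stride=2, padding=1, rng=rng)
        self.cbam = CBAM(out_ch, reduction, spatial_kernel, rng=rng)

    def forward(self, x: Tensor):
        h = self.pre(x).leaky_relu()
        for block in self.res:
            h = block(h)
        skip = h
        return self.cbam(self.down(h).leaky_relu()), skip


class _UpStage(Module):
    def __init__(self, in_ch, skip_ch, out_ch, n_res, reduction, spatial_kernel, rng):
        self.cbam = CBAM(in_ch, reduction, spatial_kernel, rng=rng)
        self.up_conv = Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.merge = Conv2d(out_ch + skip_ch, out_ch, 3, padding=1, rng=rng)
        self.res = [ResidualBlock(out_ch, rng=rng) for _ in range(n_res)]

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        h = self.up_conv(self.cbam(x).upsample2x()).relu()
        h = self.merge(concat([h, skip], axis=1)).relu()
        for block in self.res:
            h = block(h)
        return h


class Generator(Module):
    """Residual attention U-Net; output head is a sigmoid over [0, 1] labels."""

    def __init__(self, cfg: GeneratorConfig, rng=None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        chans = [min(cfg.base_channels * 2**i, 64) for i in range(cfg.depth)]
        self.downs = []
        in_ch = cfg.in_channels
        for c in chans:
            self.downs.append(
                _DownStage(in_ch, c, cfg.residual_blocks,
                           cfg.cbam_reduction_ratio, cfg.cbam_spatial_kernel, rng)
            )
            in_ch = c
        self.bottleneck = ResidualBlock(chans[-1], rng=rng)
        self.ups = []
        for i in reversed(range(cfg.depth)):
            out_c = chans[i - 1] if i > 0 else cfg.base_channels
            self.ups.append(
                _UpStage(chans[i], chans[i], out_c, cfg.residual_blocks,
                         cfg.cbam_reduction_ratio, cfg.cbam_spatial_kernel, rng)
            )
        # outermost identity skip: the head sees the raw input alongside the
        # decoder features, since the reflectance-to-coefficient map is
        # largely pointwise
        self.head = Conv2d(
            self.ups[-1].merge.weight.shape[0] + cfg.in_channels,
            cfg.out_channels, 3, padding=1, rng=rng,
        )

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for stage in self.downs:
            h, skip = stage(h)
            skips.append(skip)
        h = self.bottleneck(h)
        for stage, skip in zip(self.ups, reversed(skips)):
            h = stage(h, skip)
        return self.head(concat([h, x], axis=1)).sigmoid()

    @property
    def n_cbam(self) -> int:
        return len(self.downs) + len(self.ups)


class Discriminator(Module):
    """Three convolutional layers -> patch probability grid in (0, 1)."""

    def __init__(self, cfg: DiscriminatorConfig, rng=None):
        rng = rng or np.random.default_rng(0)
        c1, c2 = cfg.channels
        self.conv1 = Conv2d(cfg.in_channels, c1, 4, stride=2, padding=1, rng=rng)
        self.conv2 = Conv2d(c1, c2, 4, stride=2, padding=1, rng=rng)
        self.norm2 = InstanceNorm2d(c2)
        self.conv3 = Conv2d(c2, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        h = concat([x, y], axis=1)
        h = self.conv1(h).leaky_relu()
        h = self.norm2(self.conv2(h)).leaky_relu()
        return self.conv3(h).sigmoid()


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(cfg, rng=np.random.default_rng(seed))


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> Discriminator:
    return Discriminator(cfg, rng=np.random.default_rng(seed))


def assemble_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Concatenate input and label along the width into one composite image."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0] or x.shape[2:] != y.shape[2:]:
        raise ValueError("input and label must agree in height and channels")
    return np.concatenate([x, y], axis=1)


def split_pair(composite: np.ndarray):
    """Invert :func:`assemble_pair`: left half is the input, right the label."""
    composite = np.asarray(composite)
    w = composite.shape[1]
    if w % 2:
        raise ValueError("composite width must be even")
    return composite[:, : w // 2], composite[:, w // 2 :]
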