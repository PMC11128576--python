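"""Reference-hallucinating generator G.

G maps a fused image of arbitrary quality, I_org, to an estimate of the
best-quality fusion of the same scene, I_hq = G(I_org). Its only purpose is to
supply reference information to the quality network — not to produce
clinically usable fusions. Architecture: a down-sampling residual encoder, a
stack of five Unique Feature Warehouse (UFW) blocks operating at one quarter
of the input resolution (32 x 32 for 128 x 128 inputs), and a four-layer
up-sampling decoder ending in a Sigmoid.

The UFW block recognizes spatial features at three scales (full, 1/2, 1/4 via
average pooling), processes each with a 3 x 3 conv + LeakyReLU + BN branch,
up-samples the coarser branches back, fuses the branches by channel
concatenation and a 3 x 3 merge convolution, and adds a skip connection from
the block input — the "overlapping" integration that lets the network weigh
multi-scale evidence repeatedly.

All kernels are 3 x 3. Batch normalization is placed after the activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Module, Tensor, avg_pool2d, concat,
                 upsample_nearest)

_EPS = 1e-7


@dataclass
class GeneratorConfig:
    in_size: int = 128
    in_channels: int = 3
    base_channels: int = 32
    n_down_blocks: int = 3
    n_ufw_repeats: int = 5
    n_up_layers: int = 4
    kernel_size: int = 3
    leaky_slope: float = 0.2
    theta: float = 0.5  # content-loss weight in the generator objective
    use_ufw: bool = True  # ablation switch: False gives the plain encoder-decoder

    def __post_init__(self):
        if self.kernel_size != 3:
            raise ValueError("kernel size is fixed at 3 x 3")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")

    @property
    def ufw_size(self) -> int:
        return self.in_size // 4

    @property
    def ufw_channels(self) -> int:
        return 2 * self.base_channels


class ResidualBlock(Module):
    """Three 3x3 convolutions (each + LeakyReLU + BN) with a skip connection;
    channel- and resolution-preserving."""

    def __init__(self, ch: int, slope: float, rng):
        super().__init__()
        self.slope = slope
        self.convs = [Conv2d(ch, ch, rng=rng) for _ in range(3)]
        self.bns = [BatchNorm2d(ch) for _ in range(3)]

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for conv, bn in zip(self.convs, self.bns):
            y = bn(conv(y).leaky_relu(self.slope))
        return y + x


class DownBlock(Module):
    """conv(3x3, stride 2 or 1) -> LeakyReLU -> BN -> residual block."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, slope: float, rng):
        super().__init__()
        self.stride = stride
        self.slope = slope
        self.conv = Conv2d(in_ch, out_ch, stride=stride, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.res = ResidualBlock(out_ch, slope, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x.shape[2]
        if self.stride == 2 and h % 2 != 0:
            raise ValueError(f"down_block: odd spatial size {h} cannot be halved")
        return self.res(self.bn(self.conv(x).leaky_relu(self.slope)))


class UFWBlock(Module):
    """Multi-scale overlapping feature block; resolution- and channel-preserving."""

    SCALES = (1, 2, 4)  # pooling factors: full, half, quarter resolution

    def __init__(self, ch: int, size: int, slope: float, rng):
        super().__init__()
        self.size = size
        self.slope = slope
        self.branch_convs = [Conv2d(ch, ch, rng=rng) for _ in self.SCALES]
        self.branch_bns = [BatchNorm2d(ch) for _ in self.SCALES]
        self.merge = Conv2d(ch * len(self.SCALES), ch, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h != self.size or w != self.size:
            raise ValueError(
                f"ufw_block expects {self.size}x{self.size} input, got {h}x{w}")
        branches = []
        for k, conv, bn in zip(self.SCALES, self.branch_convs, self.branch_bns):
            y = avg_pool2d(x, k) if k > 1 else x
            y = bn(conv(y).leaky_relu(self.slope))
            if k > 1:
                y = upsample_nearest(y, k)
            branches.append(y)
        return self.merge(concat(branches, axis=1)) + x


class UpLayer(Module):
    """[upsample x2] -> conv 3x3 -> BN -> activation (LeakyReLU or Sigmoid)."""

    def __init__(self, in_ch: int, out_ch: int, upsample: bool, slope: float,
                 final: bool, rng):
        super().__init__()
        self.upsample = upsample
        self.final = final
        self.slope = slope
        self.conv = Conv2d(in_ch, out_ch, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.upsample:
            x = upsample_nearest(x, 2)
        y = self.bn(self.conv(x))
        if self.final:
            # clamp away from exact 0/1: float32 sigmoid saturates, and the
            # output contract (and the logs downstream) need the open interval
            return y.sigmoid().clamp(lo=1e-6, hi=1.0 - 1e-6)
        return y.leaky_relu(self.slope)


class Generator(Module):
    """I_hq = G(I_org); `features()` additionally returns F_last, the output
    of the last UFW block (consumed by the quality network)."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config.base_channels
        chans = [config.in_channels, c, 2 * c, 2 * c][: config.n_down_blocks + 1]
        size = config.in_size
        self.down_blocks = []
        for i in range(config.n_down_blocks):
            stride = 2 if size > config.ufw_size else 1
            self.down_blocks.append(
                DownBlock(chans[i], chans[i + 1], stride, config.leaky_slope, rng))
            size //= stride
        if size != config.ufw_size:
            raise ValueError(
                f"encoder ends at {size}, expected {config.ufw_size}")
        k = config.ufw_channels
        self.ufw_blocks = ([UFWBlock(k, config.ufw_size, config.leaky_slope, rng)
                            for _ in range(config.n_ufw_repeats)]
                           if config.use_ufw else [])
        # decoder: the first two of the four layers up-sample (quarter -> full
        # resolution); the last two refine at full resolution.
        dec_chans = [k, k, c, max(c // 2, 4), config.in_channels]
        self.up_layers = []
        for i in range(config.n_up_layers):
            self.up_layers.append(UpLayer(
                dec_chans[i], dec_chans[i + 1], upsample=i < 2,
                slope=config.leaky_slope, final=i == config.n_up_layers - 1,
                rng=rng))

    def _check_input(self, x: Tensor) -> None:
        s, c = self.config.in_size, self.config.in_channels
        if x.ndim != 4 or x.shape[1] != c or x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"generator expects (N, {c}, {s}, {s}) input, got {x.shape}")

    def features(self, x: Tensor) -> tuple[Tensor, Tensor]:
        self._check_input(x)
        y = x
        for blk in self.down_blocks:
            y = blk(y)
        for blk in self.ufw_blocks:
            y = blk(y)
        f_last = y
        for layer in self.up_layers:
            y = layer(y)
        return y, f_last

    def forward(self, x: Tensor) -> Tensor:
        return self.features(x)[0]


# -------------------------------------------------------------------- losses
def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def loss_content(i_hq, i_gt) -> Tensor:
    """Mean squared error between the generated image and the group reference."""
    i_hq, i_gt = _as_tensor(i_hq), _as_tensor(i_gt)
    if i_hq.shape != i_gt.shape:
        raise ValueError(f"shape mismatch: {i_hq.shape} vs {i_gt.shape}")
    return ((i_hq - i_gt) ** 2).mean()


def adversarial_term(d_fake: Tensor, eps: float = _EPS) -> Tensor:
    """mean log(1 - D(G(I_org))), epsilon-clamped inside the log."""
    if np.any(d_fake.data <= 0) or np.any(d_fake.data >= 1):
        raise ValueError("discriminator outputs must lie in (0, 1)")
    return (1.0 - d_fake).clamp(lo=eps).log().mean()


def loss_generator(i_org, i_gt, generator: Generator, discriminator,
                   theta: float | None = None) -> Tensor:
    """Generator objective: log(1 - D(G(I_org))) + theta * MSE(G(I_org), I_GT)."""
    cfg_theta = generator.config.theta if theta is None else theta
    i_org, i_gt = _as_tensor(i_org), _as_tensor(i_gt)
    i_hq = generator(i_org)
    return adversarial_term(discriminator(i_hq)) + cfg_theta * loss_content(i_hq, i_gt)
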