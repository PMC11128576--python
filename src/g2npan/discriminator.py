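"""Discriminator D and its quality-weighted adversarial objective.

D is a four-layer strided CNN (3x3 kernels, stride 2, padding 1; LeakyReLU
then BN per layer) followed by an independent classifier convolution, global
average pooling, and a sigmoid, yielding a single probability that the input
conforms to the reference-image distribution. Each feature layer halves both
spatial dimensions: 128 -> 64 -> 32 -> 16 -> 8 for 128 x 128 input.

The adversarial objective is quality-weighted: a binary per-sample weight W
(1 when the quality network scores the generated image at MOS >= 3 — the
diagnostically safe regime — else 0) acts as the discriminator's target for
the generated sample, so ascent pushes D(G(I_org)) toward W. With W = 0 the
fake term log(1 - |D - 0|) is exactly the plain GAN form log(1 - D): below
the diagnostic threshold the discriminator trains as usual. With W = 1 it
becomes log D: generated images that already clear the MOS >= 3 bar are
treated as real, lifting the adversarial pressure off them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, Tensor

_EPS = 1e-7


@dataclass
class DiscriminatorConfig:
    in_size: int = 128
    in_channels: int = 3
    channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 3
    stride: int = 2
    padding: int = 1
    leaky_slope: float = 0.2
    conditional: bool = False  # channel-concatenated (I_GT, I_hq) variant

    def __post_init__(self):
        if (self.kernel_size, self.stride, self.padding) != (3, 2, 1):
            raise ValueError("feature layers are fixed at k=3, stride=2, pad=1")


class Discriminator(Module):
    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        in_ch = config.in_channels * (2 if config.conditional else 1)
        chans = [in_ch, *config.channels]
        self.convs = [Conv2d(chans[i], chans[i + 1], stride=2, rng=rng)
                      for i in range(len(config.channels))]
        self.bns = [BatchNorm2d(c) for c in config.channels]
        self.classifier = Conv2d(config.channels[-1], 1, stride=1, rng=rng)

    def _check_input(self, x: Tensor) -> None:
        s = self.config.in_size
        c = self.config.in_channels * (2 if self.config.conditional else 1)
        if x.ndim != 4 or x.shape[1] != c or x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"discriminator expects (N, {c}, {s}, {s}) input, got {x.shape}")

    def forward(self, x: Tensor) -> Tensor:
        """Probability in (0, 1) per sample, shape (N,)."""
        self._check_input(x)
        y = x
        for conv, bn in zip(self.convs, self.bns):
            y = bn(conv(y).leaky_relu(self.config.leaky_slope))
        prob = self.classifier(y).mean(axis=(1, 2, 3)).sigmoid()
        return prob.clamp(lo=1e-6, hi=1.0 - 1e-6)  # keep strictly inside (0,1)

    def spatial_trace(self, x: Tensor) -> list[int]:
        """Spatial sizes entering/leaving each feature layer (for inspection)."""
        self._check_input(x)
        trace = [x.shape[2]]
        y = x
        for conv, bn in zip(self.convs, self.bns):
            y = bn(conv(y).leaky_relu(self.config.leaky_slope))
            trace.append(y.shape[2])
        return trace


def quality_weight(aqa_score_1to5) -> np.ndarray | int:
    """Binary perceptual weight: 1 where the predicted MOS is >= 3 (the
    diagnostically safe threshold), else 0."""
    arr = np.asarray(aqa_score_1to5, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("quality score must be finite")
    w = (arr >= 3.0).astype(np.int64)
    return int(w) if np.isscalar(aqa_score_1to5) or arr.ndim == 0 else w


def loss_discriminator(d_real: Tensor, d_fake: Tensor, w, eps: float = _EPS) -> Tensor:
    """Quality-weighted discriminator objective (to be *maximized*):

        mean log D(I_GT) + mean log(1 - |D(G(I_org)) - W|)

    with per-sample W in {0, 1} and epsilon clamping inside the logs.
    Reduces to the unweighted GAN objective exactly where W = 0.
    """
    w = np.asarray(w, dtype=np.float32).reshape(-1)
    if d_real.data.shape[0] != d_fake.data.shape[0]:
        raise ValueError(
            f"batch size mismatch: {d_real.data.shape[0]} real vs "
            f"{d_fake.data.shape[0]} fake")
    if w.shape[0] != d_fake.data.shape[0]:
        raise ValueError(
            f"weight batch size {w.shape[0]} != fake batch {d_fake.data.shape[0]}")
    if not np.all(np.isin(w, (0.0, 1.0))):
        raise ValueError("weights must be binary")
    real_term = d_real.clamp(lo=eps).log().mean()
    fake_term = (1.0 - (d_fake - Tensor(w)).abs()).clamp(lo=eps).log().mean()
    return real_term + fake_term
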