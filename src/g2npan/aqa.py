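"""Attention-based quality assessment network (AQA).

The AQA scores a fused image by looking at the image together with its
*nuance map* — the per-pixel absolute difference between the image and the
GAN-hallucinated best-quality version of the same scene:

    I_sub = |I_hq - I_org|

Image and nuance each pass a separate stem convolution, are channel
concatenated, and traverse a VGG11-style convolutional trunk. Before the
fully connected head, the trunk's globally pooled feature vector is
concatenated with the channel-wise global average of F_last (the generator's
last UFW feature map), giving the head access to the generator's
low-resolution evidence. The head maps this concatenated vector through two
fully connected layers to a raw score Q_pre; sigma(Q_pre) in (0, 1) is the
normalized quality, trained with a continuous-target binary cross entropy
against the normalized MOS.

A class activation map (CAM) is formed from the last convolutional features
using the head's weights as a cue, min-max normalized to [0, 1], and
supervised with an L1 loss against a ground-truth attention map (in the
synthetic pipeline, the known distortion-severity map); this steers the
network's attention toward the quality-relevant regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Linear, Module, Tensor, concat,
                 max_pool2d, softplus)

_EPS = 1e-8

# VGG11 convolutional plan: channel multipliers (x base width / 64) and the
# conv indices after which VGG11 places a max-pool.
_VGG11_CHANNELS = (64, 128, 256, 256, 512, 512, 512, 512)
_VGG11_POOL_AFTER = frozenset({0, 1, 3, 5, 7})


@dataclass
class AQAConfig:
    in_size: int = 128
    in_channels: int = 3
    base_width: int = 64        # width of the first trunk conv (VGG11: 64)
    stem_channels: int = 16     # per-stem channels before concatenation
    flast_channels: int = 64    # channels of the generator's F_last map
    hidden: int = 64            # width of the first fully connected layer
    cam_size: int = 4           # spatial size of the last conv map / CAM
    phi: float = 1.0            # CAM-loss weight
    use_nuance: bool = True     # feed I_sub through a second stem
    use_flast: bool = True      # concatenate pooled F_last before the head
    use_cam: bool = True        # CAM supervision on
    pretrained_path: str | None = None  # optional trunk weights (npz); off

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError("phi must be non-negative")


# ---------------------------------------------------------- pure operations
def compute_nuance(i_hq, i_org):
    """Nuance map |I_hq - I_org|; symmetric, zero iff the images coincide.

    Accepts numpy arrays (returns an array) or autograd tensors (returns a
    tensor, so gradients can flow into the generator through the nuance).
    """
    if isinstance(i_hq, Tensor) or isinstance(i_org, Tensor):
        a = i_hq if isinstance(i_hq, Tensor) else Tensor(i_hq)
        b = i_org if isinstance(i_org, Tensor) else Tensor(i_org)
        if a.shape != b.shape:
            raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
        return (a - b).abs()
    a, b = np.asarray(i_hq), np.asarray(i_org)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def compute_cam(last_conv_features: np.ndarray, weights: np.ndarray,
                normalize: bool = True) -> np.ndarray:
    """CAM(x, y) = sum_j w_j * f_j(x, y), min-max normalized to [0, 1].

    `last_conv_features` is (h, w, k); `weights` has length k and holds the
    head-weight entries for the spatially resolved trunk channels only
    (pooled F_last entries are excluded by the caller). A constant raw map
    normalizes to all zeros. ``normalize=False`` returns the raw weighted sum.
    """
    f = np.asarray(last_conv_features, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64).reshape(-1)
    if f.ndim != 3 or f.shape[2] != w.shape[0]:
        raise ValueError(
            f"feature channels {f.shape} incompatible with {w.shape[0]} weights")
    raw = np.tensordot(f, w, axes=([2], [0]))
    if not normalize:
        return raw
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _minmax_norm(t: Tensor) -> Tensor:
    """Per-sample min-max normalization of (N, h, w) maps to [0, 1];
    constant maps go to zero via the epsilon in the denominator."""
    n, h, w = t.shape
    flat = t.reshape(n, h * w)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    return ((flat - lo) / (hi - lo + _EPS)).reshape(n, h, w)


def sigmoid_map(q_pre):
    """sigma(Q_pre) = 1 / (1 + exp(-Q_pre)): raw score -> (0, 1)."""
    if isinstance(q_pre, Tensor):
        return q_pre.sigmoid()
    z = np.asarray(q_pre, dtype=np.float64)
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                   np.exp(z) / (1.0 + np.exp(z)))
    return float(out) if out.ndim == 0 else out


def normalize_mos(mos):
    """[1, 5] MOS -> [0, 1] training target."""
    arr = np.asarray(mos, dtype=np.float64)
    if np.any(arr < 1.0) or np.any(arr > 5.0):
        raise ValueError(f"MOS outside [1, 5]: {mos}")
    out = (arr - 1.0) / 4.0
    return float(out) if out.ndim == 0 else out


def denormalize_mos(score01):
    """[0, 1] score -> [1, 5] MOS scale (inverse of :func:`normalize_mos`)."""
    arr = np.asarray(score01, dtype=np.float64)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"normalized score outside [0, 1]: {score01}")
    out = 1.0 + 4.0 * arr
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------- losses
def loss_cam(f_cam, f_gt) -> Tensor:
    """L1 distance between the predicted CAM and its ground truth, averaged
    over pixels and batch."""
    f_cam = f_cam if isinstance(f_cam, Tensor) else Tensor(f_cam)
    f_gt = f_gt if isinstance(f_gt, Tensor) else Tensor(f_gt)
    if f_cam.shape != f_gt.shape:
        raise ValueError(f"shape mismatch: {f_cam.shape} vs {f_gt.shape}")
    return (f_cam - f_gt).abs().mean()


def loss_quality(q_pre, q_t) -> Tensor:
    """Continuous-target binary cross entropy on the raw score:

        -[q_t log sigma(q_pre) + (1 - q_t) log(1 - sigma(q_pre))]

    computed in the numerically stable softplus form; minimized (value = the
    entropy of q_t) exactly when sigma(q_pre) = q_t.
    """
    q_t_arr = np.asarray(q_t, dtype=np.float32)
    if np.any(q_t_arr < 0) or np.any(q_t_arr > 1):
        raise ValueError(f"quality target outside [0, 1]: {q_t}")
    z = q_pre if isinstance(q_pre, Tensor) else Tensor(q_pre)
    qt = Tensor(q_t_arr)
    return (qt * softplus(-z) + (1.0 - qt) * softplus(z)).mean()


def loss_aqa(l_cam, l_qa, phi: float = 1.0):
    """Total AQA objective: phi * L_CAM + L_QA."""
    if phi < 0:
        raise ValueError("phi must be non-negative")
    return phi * l_cam + l_qa


# -------------------------------------------------------------------- network
@dataclass
class AQAOutput:
    q_pre: Tensor        # (N,) raw scores
    q_sigmoid: Tensor    # (N,) sigma(q_pre)
    f_cam: Tensor        # (N, h', w') normalized attention maps
    f_conca: Tensor      # (N, K [+ K_flast]) concatenated head input

    @property
    def mos(self) -> np.ndarray:
        """Predicted scores on the 1-5 MOS scale."""
        return denormalize_mos(self.q_sigmoid.data.astype(np.float64))


class AQANetwork(Module):
    def __init__(self, config: AQAConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config.in_channels
        self.stem_org = Conv2d(c, config.stem_channels, rng=rng)
        self.stem_sub = (Conv2d(c, config.stem_channels, rng=rng)
                         if config.use_nuance else None)
        trunk_in = config.stem_channels * (2 if config.use_nuance else 1)
        scale = config.base_width / 64.0
        self.trunk_convs, self.trunk_bns, self._pool_after = [], [], []
        size, prev = config.in_size, trunk_in
        for i, ch64 in enumerate(_VGG11_CHANNELS):
            ch = max(int(round(ch64 * scale)), 4)
            self.trunk_convs.append(Conv2d(prev, ch, rng=rng))
            self.trunk_bns.append(BatchNorm2d(ch))
            pool = i in _VGG11_POOL_AFTER and size > config.cam_size
            self._pool_after.append(pool)
            if pool:
                size //= 2
            prev = ch
        if size != config.cam_size:
            raise ValueError(
                f"trunk ends at {size}x{size}, expected {config.cam_size}")
        self.trunk_out_channels = prev
        head_in = prev + (config.flast_channels if config.use_flast else 0)
        self.fc1 = Linear(head_in, config.hidden, rng=rng)
        self.fc2 = Linear(config.hidden, 1, rng=rng)
        if config.pretrained_path is not None:
            state = dict(np.load(config.pretrained_path))
            self.load_state_dict(state)

    # CAM cue: the head is two linear maps; the composite linear map
    # fc2.W @ fc1.W, restricted to the spatially resolved trunk channels,
    # plays the role of "the last fully connected layer's weights".
    def _cam_weights(self) -> Tensor:
        k = self.trunk_out_channels
        return (self.fc1.weight @ self.fc2.weight)[:k, 0]

    def forward(self, i_org, i_sub=None, f_last=None) -> AQAOutput:
        x = i_org if isinstance(i_org, Tensor) else Tensor(i_org)
        self._check_image(x, "I_org")
        feats = [self.stem_org(x)]
        if self.config.use_nuance:
            if i_sub is None:
                raise ValueError("nuance map I_sub required (use_nuance=True)")
            s = i_sub if isinstance(i_sub, Tensor) else Tensor(i_sub)
            self._check_image(s, "I_sub")
            feats.append(self.stem_sub(s))
        y = concat(feats, axis=1) if len(feats) > 1 else feats[0]
        for conv, bn, pool in zip(self.trunk_convs, self.trunk_bns,
                                  self._pool_after):
            y = bn(conv(y).relu())
            if pool:
                y = max_pool2d(y, 2)
        f_spatial = y  # (N, K, h', w')
        gap = f_spatial.mean(axis=(2, 3))  # (N, K)
        if self.config.use_flast:
            if f_last is None:
                raise ValueError(
                    "F_last required (use_flast=True); pass the generator's "
                    "last UFW feature map or configure the trunk-only ablation")
            fl = f_last if isinstance(f_last, Tensor) else Tensor(f_last)
            f_conca = concat([gap, fl.mean(axis=(2, 3))], axis=1)
        else:
            f_conca = gap
        q_pre = self.fc2(self.fc1(f_conca).relu())[:, 0]
        cam_raw = (f_spatial * self._cam_weights().reshape(1, -1, 1, 1)).sum(axis=1)
        f_cam = _minmax_norm(cam_raw)
        return AQAOutput(q_pre=q_pre, q_sigmoid=q_pre.sigmoid(),
                         f_cam=f_cam, f_conca=f_conca)

    def _check_image(self, x: Tensor, name: str) -> None:
        s, c = self.config.in_size, self.config.in_channels
        if x.ndim != 4 or x.shape[1] != c or x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"{name} must be (N, {c}, {s}, {s}), got {x.shape}")


def severity_to_cam_target(severity_maps: np.ndarray, cam_size: int) -> np.ndarray:
    """Ground-truth attention: block-mean downsample of the (N, H, W) severity
    maps to the CAM resolution, then per-sample min-max normalization
    (constant maps -> zeros)."""
    sev = np.asarray(severity_maps, dtype=np.float64)
    n, h, w = sev.shape
    if h % cam_size or w % cam_size:
        raise ValueError(f"severity map size {h} not divisible by {cam_size}")
    bh, bw = h // cam_size, w // cam_size
    coarse = sev.reshape(n, cam_size, bh, cam_size, bw).mean(axis=(2, 4))
    lo = coarse.min(axis=(1, 2), keepdims=True)
    hi = coarse.max(axis=(1, 2), keepdims=True)
    rng_ = hi - lo
    out = np.where(rng_ < 1e-12, 0.0, (coarse - lo) / np.maximum(rng_, 1e-12))
    return out
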