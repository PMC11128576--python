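"""Joint training of generator, discriminator, and quality network.

Each batch runs three alternating steps in the order D -> G -> AQA:

* **D step** (gradient ascent): maximize the quality-weighted objective
  ``mean log D(I_GT) + mean log(1 - |D(G(I_org)) - W|)``, with the per-sample
  binary weight W computed from the current quality network's score of the
  generated image (W = 1 when that score is in the diagnostically safe
  MOS >= 3 regime).
* **G step**: minimize ``log(1 - D(G(I_org))) + theta * MSE(G(I_org), I_GT)
  + gamma * L_R``, where L_R is the quality network's own loss evaluated on
  the freshly generated images — the generated images must satisfy not only
  the discriminator but also the quality network.
* **AQA step**: minimize ``phi * L_CAM + L_QA`` on (I_org, I_sub) pairs,
  with I_sub recomputed from the *just-updated* generator so the nuance the
  quality network learns from is never stale.

Optimization uses Adam with an initial learning rate of 2e-4 decayed by 0.95
every 20 batches. Model selection follows a grouped five-fold protocol: folds
partition *source pairs* (never images of one pair across folds), validation
metrics are computed at the end of every epoch, and the checkpoint with the
best validation metric is retained.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .aqa import (AQAConfig, AQANetwork, compute_nuance, denormalize_mos,
                  loss_aqa, loss_cam, loss_quality, normalize_mos,
                  severity_to_cam_target, sigmoid_map)
from .dataset import ImageGroup
from .discriminator import (Discriminator, DiscriminatorConfig,
                            loss_discriminator, quality_weight)
from .generator import (Generator, GeneratorConfig, adversarial_term,
                        loss_content)
from .nn import Adam, Tensor, no_grad


@dataclass
class TrainConfig:
    # protocol
    image_size: int = 128
    epochs: int = 200          # desk-scale default; the full protocol uses 1500
    batch_size: int = 8
    lr0: float = 2e-4
    decay: float = 0.95
    decay_every_batches: int = 20
    theta: float = 0.5         # content-loss weight (generator)
    phi: float = 1.0           # CAM-loss weight (quality network)
    gamma: float = 0.01        # quality-feedback weight in the total objective
    n_folds: int = 5
    seed: int = 0
    checkpoint_metric: str = "srcc"  # or "plcc"
    eval_repeats: int = 10
    eval_every: int = 1  # validate every k-th epoch (the last is always run)
    # model scale (desk-size networks are reachable by shrinking these)
    gen_base_channels: int = 32
    disc_channels: tuple[int, ...] = (32, 64, 128, 256)
    aqa_base_width: int = 64
    aqa_stem_channels: int = 16
    aqa_hidden: int = 64
    # ablation ladder: VGG11-only -> +GAN (G2N) -> +UFW (G2NN)
    # -> +perceptual weighting (G2NPN) -> +CAM (G2NPAN, the full model)
    use_gan: bool = True
    use_ufw: bool = True
    use_perceptual_weight: bool = True
    use_cam: bool = True

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.checkpoint_metric not in ("srcc", "plcc"):
            raise ValueError("checkpoint_metric must be 'srcc' or 'plcc'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["disc_channels"] = list(self.disc_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "disc_channels" in d:
            d["disc_channels"] = tuple(d["disc_channels"])
        return cls(**d)


@dataclass
class ModelState:
    """Parameters and optimizers of the three networks plus bookkeeping."""

    generator: Generator | None
    discriminator: Discriminator | None
    aqa: AQANetwork
    config: TrainConfig
    optimizers: dict = field(default_factory=dict)
    batch_counter: int = 0
    best: dict | None = None  # {"epoch", "metric", "states"}

    def eval(self):
        for net in (self.generator, self.discriminator, self.aqa):
            if net is not None:
                net.eval()
        return self

    def train(self):
        for net in (self.generator, self.discriminator, self.aqa):
            if net is not None:
                net.train()
        return self

    def predict_mos(self, pixels: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Predicted MOS (1-5 scale) for a stack of (N, H, W, 3) images."""
        self.eval()
        x_all = np.transpose(np.asarray(pixels, dtype=np.float32), (0, 3, 1, 2))
        preds = []
        with no_grad():
            for lo in range(0, x_all.shape[0], batch_size):
                xb = Tensor(x_all[lo:lo + batch_size])
                if self.generator is not None:
                    i_hq, f_last = self.generator.features(xb)
                    i_sub = compute_nuance(i_hq, xb)
                    out = self.aqa(xb, i_sub,
                                   f_last if self.aqa.config.use_flast else None)
                else:
                    out = self.aqa(xb)
                preds.append(out.mos)
        return np.concatenate(preds)


def lr_schedule(batch_index: int, cfg: TrainConfig) -> float:
    """lr0 * decay^floor(batch_index / decay_every_batches)."""
    if batch_index < 0:
        raise ValueError("batch index must be non-negative")
    return cfg.lr0 * cfg.decay ** (batch_index // cfg.decay_every_batches)


def five_fold_split(groups, seed: int, n_folds: int = 5):
    """Grouped cross-validation folds: partition *group ids* (source pairs),
    so no scene contributes images to both sides of a split."""
    ids = [g.group_id if isinstance(g, ImageGroup) else int(g) for g in groups]
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} groups, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF0)))
    perm = rng.permutation(np.asarray(ids))
    folds = np.array_split(perm, n_folds)
    out = []
    for i, test in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        out.append((sorted(int(x) for x in train), sorted(int(x) for x in test)))
    return out


def build_models(cfg: TrainConfig) -> ModelState:
    """Instantiate G, D, AQA (as the ablation flags require), deterministically
    from cfg.seed."""
    ss = np.random.SeedSequence((cfg.seed, 0xB11D))
    rng_g, rng_d, rng_a = (np.random.default_rng(s) for s in ss.spawn(3))
    gen = disc = None
    if cfg.use_gan:
        gen = Generator(GeneratorConfig(
            in_size=cfg.image_size, base_channels=cfg.gen_base_channels,
            theta=cfg.theta, use_ufw=cfg.use_ufw), rng_g)
        disc = Discriminator(DiscriminatorConfig(
            in_size=cfg.image_size, channels=cfg.disc_channels), rng_d)
    aqa = AQANetwork(AQAConfig(
        in_size=cfg.image_size, base_width=cfg.aqa_base_width,
        stem_channels=cfg.aqa_stem_channels, hidden=cfg.aqa_hidden,
        flast_channels=2 * cfg.gen_base_channels, phi=cfg.phi,
        use_nuance=cfg.use_gan, use_flast=cfg.use_gan,
        use_cam=cfg.use_cam), rng_a)
    state = ModelState(generator=gen, discriminator=disc, aqa=aqa, config=cfg)
    state.optimizers = {
        name: Adam(net.parameters(), lr=cfg.lr0)
        for name, net in (("generator", gen), ("discriminator", disc),
                          ("aqa", aqa)) if net is not None}
    return state


def _flatten(groups: list[ImageGroup]):
    """Stack group images into arrays: X, reference GT, targets, CAM GT."""
    xs, gts, mos, sevs = [], [], [], []
    for g in groups:
        ref = g.reference.pixels
        for v in g.variants:
            xs.append(v.pixels)
            gts.append(ref)
            mos.append(v.mos)
            sevs.append(v.severity_map)
    x = np.transpose(np.stack(xs), (0, 3, 1, 2)).astype(np.float32)
    gt = np.transpose(np.stack(gts), (0, 3, 1, 2)).astype(np.float32)
    mos = np.asarray(mos, dtype=np.float64)
    sev = (np.stack(sevs).astype(np.float32)
           if all(s is not None for s in sevs) else None)
    return x, gt, mos, sev


def _check_finite(value: float, component: str, batch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite value in {component} loss at batch {batch}; aborting")


def _zero_all(state: ModelState) -> None:
    for net in (state.generator, state.discriminator, state.aqa):
        if net is not None:
            net.zero_grad()


def train_batch(state: ModelState, xb: np.ndarray, gtb: np.ndarray,
                qtb: np.ndarray, fgtb: np.ndarray | None) -> dict:
    """One D -> G -> AQA alternation on a single batch. Returns the losses."""
    cfg = state.config
    lr = lr_schedule(state.batch_counter, cfg)
    for opt in state.optimizers.values():
        opt.lr = lr
    x_t, gt_t = Tensor(xb), Tensor(gtb)
    losses = {"lr": lr}

    if cfg.use_gan:
        # one generator forward serves the D step (detached) and the G step
        i_hq, f_last = state.generator.features(x_t)
        if not np.all(np.isfinite(i_hq.data)):
            raise RuntimeError(
                f"non-finite value in generator output at batch "
                f"{state.batch_counter}; aborting")
        i_hq_frozen = i_hq.detach()
        # ---- D step (ascent on the quality-weighted objective)
        with no_grad():
            if cfg.use_perceptual_weight:
                # scoring I_hq is an inference call: eval mode, so the AQA's
                # batch-norm running statistics are not polluted by generated
                # images and zero nuance maps
                state.aqa.eval()
                zero_nuance = Tensor(np.zeros_like(i_hq_frozen.data))
                w_scores = denormalize_mos(sigmoid_map(
                    state.aqa(i_hq_frozen, zero_nuance,
                              Tensor(f_last.data) if state.aqa.config.use_flast
                              else None).q_pre.data.astype(np.float64)))
                w = quality_weight(w_scores)
                state.aqa.train()
            else:
                w = np.ones(xb.shape[0], dtype=np.int64)
        d_obj = loss_discriminator(state.discriminator(gt_t),
                                   state.discriminator(i_hq_frozen), w)
        _check_finite(d_obj.item(), "discriminator", state.batch_counter)
        _zero_all(state)
        (-d_obj).backward()  # ascend
        state.optimizers["discriminator"].step()
        losses["loss_d"] = d_obj.item()

        # ---- G step (against the just-updated discriminator), sharing one
        # forward/backward with the AQA step: the generator objective already
        # contains gamma * L_R, and L_R is exactly the AQA objective, so the
        # AQA gradients deposited by this backward pass, rescaled by 1/gamma,
        # are the exact AQA-step gradients (both evaluated at the pre-update
        # parameter point, as in simultaneous GAN updates).
        adv = adversarial_term(state.discriminator(i_hq))
        l1 = loss_content(i_hq, gt_t)
        g_obj = adv + cfg.theta * l1
        joint = cfg.use_perceptual_weight and cfg.gamma > 0
        if joint:
            i_sub = compute_nuance(i_hq, x_t)
            out = state.aqa(x_t, i_sub,
                            f_last if state.aqa.config.use_flast else None)
            l_qa = loss_quality(out.q_pre, qtb)
            if cfg.use_cam and fgtb is not None:
                l_r = loss_aqa(loss_cam(out.f_cam, fgtb), l_qa, cfg.phi)
            else:
                l_r = l_qa
            g_obj = g_obj + cfg.gamma * l_r
        _check_finite(g_obj.item(), "generator", state.batch_counter)
        _zero_all(state)
        g_obj.backward()
        state.optimizers["generator"].step()
        losses["loss_g"] = g_obj.item()
        losses["mse_ref"] = l1.item()

        if joint:
            for p in state.aqa.parameters():
                if p.grad is not None:
                    p.grad = p.grad / cfg.gamma
            state.optimizers["aqa"].step()
            losses["loss_aqa"] = l_r.item()
            state.batch_counter += 1
            return losses

        # ---- separate AQA step (no quality feedback into G configured)
        i_sub2 = Tensor(compute_nuance(i_hq_frozen.data, xb))
        out = state.aqa(x_t, i_sub2,
                        Tensor(f_last.data) if state.aqa.config.use_flast
                        else None)
    else:
        out = state.aqa(x_t)

    l_qa = loss_quality(out.q_pre, qtb)
    if cfg.use_cam and fgtb is not None:
        a_obj = loss_aqa(loss_cam(out.f_cam, fgtb), l_qa, cfg.phi)
    else:
        a_obj = l_qa
    _check_finite(a_obj.item(), "aqa", state.batch_counter)
    _zero_all(state)
    a_obj.backward()
    state.optimizers["aqa"].step()
    losses["loss_aqa"] = a_obj.item()

    state.batch_counter += 1
    return losses


def _validate(state: ModelState, x: np.ndarray, gt: np.ndarray,
              batch_size: int = 64):
    """One pass over the validation images: predicted MOS and (when a
    generator is present) its MSE to the group references."""
    state.eval()
    preds, sq_err = [], 0.0
    with no_grad():
        for lo in range(0, x.shape[0], batch_size):
            xb = Tensor(x[lo:lo + batch_size])
            if state.generator is not None:
                i_hq, f_last = state.generator.features(xb)
                sq_err += float(((i_hq.data - gt[lo:lo + batch_size]) ** 2
                                 ).mean()) * xb.shape[0]
                out = state.aqa(xb, compute_nuance(i_hq, xb),
                                f_last if state.aqa.config.use_flast else None)
            else:
                out = state.aqa(xb)
            preds.append(out.mos)
    gen_mse = sq_err / x.shape[0] if state.generator is not None else None
    return np.concatenate(preds), gen_mse


def fit(train_groups: list[ImageGroup], val_groups: list[ImageGroup],
        cfg: TrainConfig, log_path: str | None = None):
    """Run the alternating training scheme; returns (ModelState, epoch log).

    The log has one row per epoch with the running training losses, the
    validation correlation metrics, the validation generator MSE to the group
    references, and the learning rate. The best checkpoint by
    ``cfg.checkpoint_metric`` is restored into the returned state.
    """
    if not train_groups:
        raise ValueError("training fold is empty")
    state = build_models(cfg)
    x, gt, mos, sev = _flatten(train_groups)
    qt = normalize_mos(mos)
    fgt = (severity_to_cam_target(sev, cfg_cam_size(cfg))
           if sev is not None else None)
    have_val = bool(val_groups)
    if have_val:
        xv, gtv, mosv, _ = _flatten(val_groups)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xF17)))
    n = x.shape[0]
    log: list[dict] = []
    fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(1, cfg.epochs + 1):
            state.train()
            perm = rng.permutation(n)
            epoch_losses: dict[str, list] = {}
            for lo in range(0, n, cfg.batch_size):
                idx = perm[lo:lo + cfg.batch_size]
                if idx.size < 2:  # batch norm needs more than one sample
                    continue
                losses = train_batch(
                    state, x[idx], gt[idx], qt[idx],
                    fgt[idx] if fgt is not None else None)
                for k, v in losses.items():
                    epoch_losses.setdefault(k, []).append(v)
            row = {"epoch": epoch,
                   **{k: float(np.mean(v)) for k, v in epoch_losses.items()}}
            if have_val and (epoch % cfg.eval_every == 0
                             or epoch == cfg.epochs or epoch == 1):
                preds, gen_mse = _validate(state, xv, gtv)
                try:
                    res = evaluation.compute_metrics(preds, mosv)
                    row.update(val_plcc=res.plcc, val_srcc=res.srcc,
                               val_krcc=res.krcc, val_rmse=res.rmse)
                except ValueError:  # degenerate (constant) predictions
                    row.update(val_plcc=float("nan"), val_srcc=float("nan"),
                               val_krcc=float("nan"), val_rmse=float("nan"))
                if gen_mse is not None:
                    row["val_gen_mse"] = gen_mse
                metric = row.get(f"val_{cfg.checkpoint_metric}", float("nan"))
                if np.isfinite(metric) and (
                        state.best is None or metric > state.best["metric"]):
                    state.best = {
                        "epoch": epoch, "metric": float(metric),
                        "states": {name: net.state_dict() for name, net in
                                   (("generator", state.generator),
                                    ("discriminator", state.discriminator),
                                    ("aqa", state.aqa)) if net is not None}}
            log.append(row)
            if fh:
                fh.write(json.dumps(row) + "\n")
    finally:
        if fh:
            fh.close()
    if state.best is not None:
        for name, net in (("generator", state.generator),
                          ("discriminator", state.discriminator),
                          ("aqa", state.aqa)):
            if net is not None:
                net.load_state_dict(state.best["states"][name])
    return state, log


def cfg_cam_size(cfg: TrainConfig) -> int:
    return AQAConfig(in_size=cfg.image_size).cam_size


# --------------------------------------------------------------- checkpoints
def save_checkpoint(path: str, state: ModelState) -> None:
    """Serialize all network parameters plus the training config (npz)."""
    arrays = {"__config__": np.frombuffer(
        json.dumps(state.config.to_dict()).encode(), dtype=np.uint8)}
    for name, net in (("generator", state.generator),
                      ("discriminator", state.discriminator),
                      ("aqa", state.aqa)):
        if net is not None:
            for k, v in net.state_dict().items():
                arrays[f"{name}/{k}"] = v
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> ModelState:
    data = np.load(path)
    cfg = TrainConfig.from_dict(
        json.loads(bytes(data["__config__"].tobytes()).decode()))
    state = build_models(cfg)
    for name, net in (("generator", state.generator),
                      ("discriminator", state.discriminator),
                      ("aqa", state.aqa)):
        if net is not None:
            prefix = f"{name}/"
            sub = {k[len(prefix):]: data[k] for k in data.files
                   if k.startswith(prefix)}
            net.load_state_dict(sub)
    return state
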