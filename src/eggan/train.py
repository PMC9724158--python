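"""Training loops: edge-detector pretraining, paired encoder-decoder
training, and unpaired edge-guided GAN training.

All loops are pure functions of (data, configs, seed): every random draw —
weight init, batch order, augmentation — comes from generators keyed by the
config seed, so rerunning with the same inputs reproduces the loss history
to floating-point tolerance.

The unpaired trainer receives only the (sources, targets) view of a sample
set; the recorded pairing permutation is never read (it exists solely so
evaluation can recover the hidden ground-truth pairing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import resize

from . import autodiff as ad
from .autodiff import Adam, SGDMomentum, Tensor
from .losses import (
    LossReport,
    LossWeights,
    cycle_and_identity,
    edge_maintenance_loss,
    lsgan_terms,
    paired_total,
)
from .nets import (
    DiscriminatorConfig,
    EdgeNetConfig,
    EdgeUNet,
    Generator,
    GeneratorConfig,
    PatchDiscriminator,
    save_checkpoint,
)
from .phantoms import Image2D, SampleSet

CANNY_SIGMA = 1.0
CANNY_LOW = 0.1   # hysteresis thresholds on the normalised [0, 1] range
CANNY_HIGH = 0.3


@dataclass
class AugmentConfig:
    """Geometric augmentation: flips, crop-and-resize-back, small rotation."""

    enabled: bool = True
    flip_prob: float = 0.5
    crop_fraction: float = 0.9       # retained area fraction
    rotation_degrees: tuple = (-5.0, 5.0)

    def __post_init__(self):
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must be in (0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 2
    learning_rate: float = 1e-4
    momentum_beta: float = 0.9
    optimizer: str = "adam"
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    checkpoint_every: int = 0  # epochs; 0 disables

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size >= 1 and learning_rate > 0 required")
        if self.optimizer not in ("adam", "sgd_momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


# Unpaired defaults: batch 4, learning rate 5e-4.
def unpaired_defaults(**overrides) -> TrainConfig:
    base = dict(epochs=100, batch_size=4, learning_rate=5e-4)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    history: list = field(default_factory=list)
    checkpoint_paths: list = field(default_factory=list)

    def log(self, report: LossReport):
        self.history.append(report)
        self.step += 1

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.history])


def _make_optimizer(params, cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return Adam(params, lr=cfg.learning_rate, beta1=cfg.momentum_beta)
    return SGDMomentum(params, lr=cfg.learning_rate, momentum=cfg.momentum_beta)


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# -- augmentation ----------------------------------------------------------

def _transform_one(img: np.ndarray, draws: dict, cfg: AugmentConfig) -> np.ndarray:
    out = img
    if draws["hflip"]:
        out = out[:, ::-1]
    if draws["vflip"]:
        out = out[::-1, :]
    if cfg.crop_fraction < 1.0:
        h, w = out.shape
        ch = max(2, int(round(h * np.sqrt(cfg.crop_fraction))))
        cw = max(2, int(round(w * np.sqrt(cfg.crop_fraction))))
        oy = int(draws["crop_y"] * (h - ch))
        ox = int(draws["crop_x"] * (w - cw))
        out = resize(out[oy:oy + ch, ox:ox + cw], (h, w), order=1,
                     preserve_range=True, anti_aliasing=False)
    if draws["angle"] != 0.0:
        out = ndimage.rotate(out, draws["angle"], reshape=False, order=1,
                             mode="nearest")
    return np.ascontiguousarray(out)


def augment_batch(batch, cfg: AugmentConfig, rng: np.random.Generator):
    """Apply per-sample geometric transforms; paired images share draws.

    ``batch`` is a list of (source, target) H x W arrays (target may be
    None for unpaired streams). Output shapes are unchanged.
    """
    if not cfg.enabled:
        return [(s.copy(), None if t is None else t.copy()) for s, t in batch]
    out = []
    for src, tgt in batch:
        draws = {
            "hflip": rng.random() < cfg.flip_prob,
            "vflip": rng.random() < cfg.flip_prob,
            "crop_y": rng.random(),
            "crop_x": rng.random(),
            "angle": rng.uniform(*cfg.rotation_degrees),
        }
        out.append((
            _transform_one(src, draws, cfg),
            None if tgt is None else _transform_one(tgt, draws, cfg),
        ))
    return out


# -- edge detector pretraining --------------------------------------------

def canny_edges(img: Image2D) -> np.ndarray:
    """Binary Canny edge map on the normalised intensity range."""
    norm = img.pixels / img.intensity_max
    return canny(norm, sigma=CANNY_SIGMA, low_threshold=CANNY_LOW,
                 high_threshold=CANNY_HIGH).astype(np.float64)


def train_edge_detector(images, cfg: TrainConfig, edge_cfg: EdgeNetConfig,
                        progress: bool = False):
    """Supervise a U-Net against Canny edge maps; return it frozen.

    Binary cross-entropy on raw scores; the resulting detector's weights are
    frozen so it can serve as the fixed edge reference inside the unpaired
    GAN.
    """
    if len(images) < 1:
        raise ValueError("need at least one training image")
    net = EdgeUNet(edge_cfg, _rng(cfg.seed, 100))
    opt = _make_optimizer(net.parameters(), cfg)
    data_rng = _rng(cfg.seed, 101)
    aug_rng = _rng(cfg.seed, 102)
    state = TrainState()
    inputs = [img.to_network() for img in images]
    targets = [canny_edges(img) for img in images]
    n = len(images)
    for epoch in range(cfg.epochs):
        order = data_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = augment_batch(
                [(inputs[i], targets[i]) for i in idx], cfg.augment, aug_rng
            )
            x = Tensor(np.stack([s for s, _ in batch])[:, None], requires_grad=False)
            # re-binarise targets after interpolation
            y = (np.stack([t for _, t in batch])[:, None] > 0.5).astype(np.float64)
            opt.zero_grad()
            loss = ad.bce_with_logits(net.forward(x), y)
            loss.backward()
            opt.step()
            state.log(LossReport(e_t=loss.item()))
        state.epoch = epoch + 1
    net.freeze()
    return net, state


def edge_dice(net: EdgeUNet, images, threshold: float = 0.5) -> float:
    """Mean Dice overlap between thresholded predictions and Canny maps."""
    scores = []
    for img in images:
        pred = net.edge_map_array(img.to_network()) > threshold
        ref = canny_edges(img) > 0.5
        inter = np.logical_and(pred, ref).sum()
        denom = pred.sum() + ref.sum()
        scores.append(1.0 if denom == 0 else 2.0 * inter / denom)
    return float(np.mean(scores))


# -- paired training -------------------------------------------------------

def _maybe_checkpoint(cfg, state, epoch, checkpoint_dir, save_fn):
    if checkpoint_dir is None or cfg.checkpoint_every <= 0:
        return
    if (epoch + 1) % cfg.checkpoint_every == 0:
        from pathlib import Path

        path = Path(checkpoint_dir) / f"epoch_{epoch + 1:04d}.npz"
        path.parent.mkdir(parents=True, exist_ok=True)
        save_fn(path)
        state.checkpoint_paths.append(str(path))


def train_paired(samples: SampleSet, gen_cfg: GeneratorConfig, cfg: TrainConfig,
                 progress: bool = False, checkpoint_dir=None):
    """Minimise the edge-sensitive composite e_L2 + e_G + e_N on paired data."""
    if not samples.paired:
        raise ValueError("train_paired requires a paired sample set")
    gen = Generator(gen_cfg, _rng(cfg.seed, 200))
    opt = _make_optimizer(gen.parameters(), cfg)
    data_rng = _rng(cfg.seed, 201)
    aug_rng = _rng(cfg.seed, 202)
    state = TrainState()
    src = [img.to_network() for img in samples.sources]
    tgt = [img.to_network() for img in samples.targets]
    n = len(samples)
    for epoch in range(cfg.epochs):
        order = data_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = augment_batch([(src[i], tgt[i]) for i in idx],
                                  cfg.augment, aug_rng)
            x = Tensor(np.stack([s for s, _ in batch])[:, None])
            y = Tensor(np.stack([t for _, t in batch])[:, None])
            opt.zero_grad()
            est = gen.forward(x)
            e_t, report = paired_total(est, y)
            e_t.backward()
            opt.step()
            state.log(report)
        state.epoch = epoch + 1
        _maybe_checkpoint(cfg, state, epoch, checkpoint_dir,
                          lambda p: save_checkpoint(p, "generator", gen_cfg, gen))
    return gen, state


# -- unpaired EGGAN training ----------------------------------------------

def train_eggan(samples: SampleSet, gen_cfg: GeneratorConfig,
                disc_cfg: DiscriminatorConfig, edge_net: EdgeUNet,
                cfg: TrainConfig, progress: bool = False, checkpoint_dir=None):
    """Alternating LSGAN training of two generators and two discriminators.

    Generator objective: e_LSGAN1 + e_LSGAN2 + lambda_cyc*e_cyc +
    lambda_iden*e_iden + lambda_em*e_EM, the edge-maintenance term computed
    through the frozen ``edge_net``. Discriminators D_B (domain B realism of
    G_AB outputs) and D_A are updated first each step, then both generators
    jointly. The sample set's pairing permutation is never consulted.
    """
    if samples.paired:
        warnings.warn("paired set passed to train_eggan; targets treated as "
                      "an unpaired pool", stacklevel=2)
    if any(p.requires_grad for p in edge_net.all_tensors()):
        raise ValueError("edge_net must be frozen before EGGAN training")
    w = cfg.loss_weights
    g_ab = Generator(gen_cfg, _rng(cfg.seed, 300))
    g_ba = Generator(gen_cfg, _rng(cfg.seed, 301))
    d_a = PatchDiscriminator(disc_cfg, _rng(cfg.seed, 302))
    d_b = PatchDiscriminator(disc_cfg, _rng(cfg.seed, 303))
    opt_g = _make_optimizer(g_ab.parameters() + g_ba.parameters(), cfg)
    opt_d = _make_optimizer(d_a.parameters() + d_b.parameters(), cfg)
    data_rng = _rng(cfg.seed, 304)
    aug_rng = _rng(cfg.seed, 305)
    state = TrainState()

    sources, targets = samples.unpaired_view()
    src = [img.to_network() for img in sources]
    tgt = [img.to_network() for img in targets]
    n = len(src)
    for epoch in range(cfg.epochs):
        order_a = data_rng.permutation(n)
        order_b = data_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            ia = order_a[start:start + cfg.batch_size]
            ib = order_b[start:start + cfg.batch_size]
            batch_a = augment_batch([(src[i], None) for i in ia], cfg.augment, aug_rng)
            batch_b = augment_batch([(tgt[i], None) for i in ib], cfg.augment, aug_rng)
            a = Tensor(np.stack([s for s, _ in batch_a])[:, None])
            b = Tensor(np.stack([s for s, _ in batch_b])[:, None])

            fake_b = g_ab.forward(a)
            fake_a = g_ba.forward(b)

            # discriminators first (fakes detached)
            opt_d.zero_grad()
            d_b_loss, _ = lsgan_terms(d_b.forward(b), d_b.forward(fake_b.detach()))
            d_a_loss, _ = lsgan_terms(d_a.forward(a), d_a.forward(fake_a.detach()))
            (d_a_loss + d_b_loss).backward()
            opt_d.step()

            # generators jointly
            opt_g.zero_grad()
            _, g_ab_adv = lsgan_terms(Tensor(np.zeros(1)), d_b.forward(fake_b))
            _, g_ba_adv = lsgan_terms(Tensor(np.zeros(1)), d_a.forward(fake_a))
            cycled_a = g_ba.forward(fake_b)
            cycled_b = g_ab.forward(fake_a)
            total = g_ab_adv + g_ba_adv
            e_cyc_val = e_iden_val = e_em_val = 0.0
            if w.use_cycle:
                e_cyc = (ad.absolute(cycled_a - a).mean()
                         + ad.absolute(cycled_b - b).mean())
                total = total + w.lambda_cyc * e_cyc
                e_cyc_val = e_cyc.item()
            if w.use_identity:
                e_iden = (ad.absolute(g_ab.forward(b) - b).mean()
                          + ad.absolute(g_ba.forward(a) - a).mean())
                total = total + w.lambda_iden * e_iden
                e_iden_val = e_iden.item()
            if w.use_edge_maintenance and w.lambda_em > 0:
                e_em = edge_maintenance_loss(edge_net, a, fake_b, cycled_a)
                if w.edge_maintenance_both_directions:
                    e_em = e_em + edge_maintenance_loss(edge_net, b, fake_a, cycled_b)
                total = total + w.lambda_em * e_em
                e_em_val = e_em.item()
            total.backward()
            opt_g.step()

            report = LossReport(
                e_lsgan_1=g_ab_adv.item(), e_lsgan_2=g_ba_adv.item(),
                e_cyc=e_cyc_val, e_iden=e_iden_val, e_em=e_em_val,
            )
            report.e_cg = (report.e_lsgan_1 + report.e_lsgan_2
                           + w.lambda_cyc * e_cyc_val + w.lambda_iden * e_iden_val)
            report.e_t = report.e_cg + w.lambda_em * e_em_val
            state.log(report)
        state.epoch = epoch + 1
        _maybe_checkpoint(cfg, state, epoch, checkpoint_dir,
                          lambda p: save_checkpoint(p, "generator", gen_cfg, g_ab))
    return (g_ab, g_ba), (d_a, d_b), state


def edge_discrepancy(edge_net: EdgeUNet, g_ab: Generator, sources) -> float:
    """Mean L1 gap between edge maps of translated images and their sources.

    The quantity the edge-maintenance term targets, measured at inference.
    """
    gaps = []
    for img in sources:
        x = img.to_network()
        f_src = edge_net.edge_map_array(x)
        f_tr = edge_net.edge_map_array(g_ab.translate(x))
        gaps.append(float(np.mean(np.abs(f_tr - f_src))))
    return float(np.mean(gaps))


def generator_ssim(gen: Generator, pairs, ssim_params=None) -> float:
    """Mean SSIM of translated sources against reference targets (12-bit)."""
    from .metrics import ssim as ssim_fn

    vals = []
    for src, ref in pairs:
        est = Image2D.from_network(gen.translate(src.to_network()),
                                   ref.intensity_max, ref.domain_tag)
        vals.append(ssim_fn(est, ref, ssim_params))
    return float(np.mean(vals))
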