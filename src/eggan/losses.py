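"""Training objectives.

Paired translation minimises an edge-sensitive composite,

    e_T = e_L2 + e_G + e_N,

where e_L2 is the mean squared intensity error, e_G the mean absolute
difference of forward-difference image gradients, and e_N one minus the
cosine between per-pixel surface normals n = [grad_x, grad_y, 1] (each
per-pixel term lies in [0, 2]; the constant third component keeps the
denominator >= 1). e_L2 removes overall intensity shifts; e_G and e_N are
sensitive to small shifts in tissue edges.

Unpaired training uses the CycleGAN composite with least-squares adversarial
terms plus an edge-maintenance penalty from a frozen edge detector F:

    e_CG = e_LSGAN1 + e_LSGAN2 + lambda_cyc * e_cyc + lambda_iden * e_iden
    e_T  = e_CG + lambda_em * e_EM

with e_EM the mean L1 discrepancy between the edge maps of the translated
and cycle-reconstructed images and the edge map of their source.

All functions accept autodiff Tensors (differentiable, used by the training
loops) or plain numpy arrays; gradients use forward differences with the
last row/column set to zero, so a pure constant shift has e_G = e_N = 0 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class LossWeights:
    """Weights and per-term toggles of the unpaired composite."""

    lambda_cyc: float = 10.0
    lambda_iden: float = 10.0
    lambda_em: float = 5.0
    use_cycle: bool = True
    use_identity: bool = True
    use_edge_maintenance: bool = True
    edge_maintenance_both_directions: bool = True

    def __post_init__(self):
        if min(self.lambda_cyc, self.lambda_iden, self.lambda_em) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossReport:
    """Scalar values of every objective term at one training step."""

    e_l2: float = 0.0
    e_g: float = 0.0
    e_n: float = 0.0
    e_t: float = 0.0
    e_em: float = 0.0
    e_cg: float = 0.0
    e_lsgan_1: float = 0.0
    e_lsgan_2: float = 0.0
    e_cyc: float = 0.0
    e_iden: float = 0.0

    FIELDS = ("e_l2", "e_g", "e_n", "e_t", "e_em", "e_cg",
              "e_lsgan_1", "e_lsgan_2", "e_cyc", "e_iden")

    def as_row(self) -> dict:
        return asdict(self)


def _pair(g_e, g_r) -> tuple[Tensor, Tensor]:
    a, b = ad.as_tensor(g_e), ad.as_tensor(g_r)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def l2_loss(g_e, g_r) -> Tensor:
    """Mean over pixels of (g_e - g_r)^2."""
    a, b = _pair(g_e, g_r)
    d = a - b
    return (d * d).mean()


def gradient_loss(g_e, g_r) -> Tensor:
    """Mean of |grad_x difference| + |grad_y difference| (forward diffs)."""
    a, b = _pair(g_e, g_r)
    gx = ad.absolute(ad.grad_x(a) - ad.grad_x(b)).mean()
    gy = ad.absolute(ad.grad_y(a) - ad.grad_y(b)).mean()
    return gx + gy


def normal_loss(g_e, g_r) -> Tensor:
    """Mean of 1 - cos(n_e, n_r) with n = [grad_x, grad_y, 1]."""
    a, b = _pair(g_e, g_r)
    ax, ay = ad.grad_x(a), ad.grad_y(a)
    bx, by = ad.grad_x(b), ad.grad_y(b)
    dot = ax * bx + ay * by + 1.0
    na = ad.sqrt(ax * ax + ay * ay + 1.0)
    nb = ad.sqrt(bx * bx + by * by + 1.0)
    return (1.0 - dot / (na * nb)).mean()


def paired_total(g_e, g_r) -> tuple[Tensor, LossReport]:
    """Composite paired objective e_T = e_L2 + e_G + e_N (unweighted sum)."""
    e_l2 = l2_loss(g_e, g_r)
    e_g = gradient_loss(g_e, g_r)
    e_n = normal_loss(g_e, g_r)
    e_t = e_l2 + e_g + e_n
    report = LossReport(e_l2=e_l2.item(), e_g=e_g.item(), e_n=e_n.item(),
                        e_t=e_t.item())
    return e_t, report


def edge_maintenance_loss(edge_net, source, translated, cycled) -> Tensor:
    """L1 discrepancy of edge maps against the source's edge map.

    mean |F(translated) - F(source)| + mean |F(cycled) - F(source)| with F
    the frozen edge detector (its parameters receive no gradients; the
    translated/cycled images do).
    """
    f_src = edge_net.edge_map(ad.as_tensor(source))
    f_src = Tensor(f_src.data)  # source edges are a fixed reference
    f_tr = edge_net.edge_map(ad.as_tensor(translated))
    f_cy = edge_net.edge_map(ad.as_tensor(cycled))
    return ad.absolute(f_tr - f_src).mean() + ad.absolute(f_cy - f_src).mean()


def lsgan_terms(scores_real, scores_fake) -> tuple[Tensor, Tensor]:
    """Least-squares adversarial objectives on raw patch scores.

    d_loss = 1/2 mean[(D(real) - 1)^2] + 1/2 mean[D(fake)^2];
    g_loss = mean[(D(fake) - 1)^2].
    """
    real = ad.as_tensor(scores_real)
    fake = ad.as_tensor(scores_fake)
    d_loss = 0.5 * ((real - 1.0) * (real - 1.0)).mean() + 0.5 * (fake * fake).mean()
    g_loss = ((fake - 1.0) * (fake - 1.0)).mean()
    return d_loss, g_loss


def cycle_and_identity(g_ab, g_ba, a, b) -> tuple[Tensor, Tensor]:
    """Cycle-consistency and identity terms (both L1).

    e_cyc  = mean|G_BA(G_AB(a)) - a| + mean|G_AB(G_BA(b)) - b|
    e_iden = mean|G_AB(b) - b| + mean|G_BA(a) - a|
    """
    a, b = ad.as_tensor(a), ad.as_tensor(b)
    e_cyc = (ad.absolute(g_ba(g_ab(a)) - a).mean()
             + ad.absolute(g_ab(g_ba(b)) - b).mean())
    e_iden = (ad.absolute(g_ab(b) - b).mean()
              + ad.absolute(g_ba(a) - a).mean())
    return e_cyc, e_iden


def eggan_total(parts: LossReport, w: LossWeights) -> float:
    """Scalar composite from already-computed parts.

    e_CG = e_LSGAN1 + e_LSGAN2 + lambda_cyc*e_cyc + lambda_iden*e_iden;
    e_T = e_CG + lambda_em*e_EM. Disabled terms contribute zero.
    """
    e_cg = parts.e_lsgan_1 + parts.e_lsgan_2
    if w.use_cycle:
        e_cg += w.lambda_cyc * parts.e_cyc
    if w.use_identity:
        e_cg += w.lambda_iden * parts.e_iden
    e_t = e_cg
    if w.use_edge_maintenance:
        e_t += w.lambda_em * parts.e_em
    parts.e_cg = e_cg
    parts.e_t = e_t
    return e_t
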