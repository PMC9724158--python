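"""Network architectures for edge-guided medical image translation.

Three families:

* ``Generator`` — an encoder-decoder translator. The encoder replaces pooling
  with strided convolutions and stacks residual blocks per level; every
  encoder level's features pass through a global-to-local dilated-convolution
  fusion block on their skip pathway before being merged into the matching
  decoder level. The decoder doubles resolution with a dual-branch
  interleaved upsampler.
* ``PatchDiscriminator`` — a PatchGAN emitting a grid of raw (LSGAN) scores.
* ``EdgeUNet`` — a small U-Net producing a single-channel edge-probability
  map; trained once against Canny targets and then frozen inside the
  unpaired GAN to compute the edge-maintenance loss.

The functional entry points ``dilated_conv`` and ``g2l_fuse`` expose the two
core primitives for direct testing against brute-force oracles.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import (
    Conv2d,
    ConvNormRelu,
    InstanceNorm2d,
    Module,
    ResidualBlock,
    same_padding,
)

MAX_CHANNELS = 512


# -- configs ---------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Hyperparameters of the encoder-decoder translator.

    ``input_size`` must be divisible by ``2**levels``; the bottleneck is
    ``input_size / 2**levels`` pixels per side (8 for the 256-pixel default)
    and must stay >= 4. ``dilation_rates`` drive the global-to-local fusion;
    aggregation proceeds from the largest rate inward.
    """

    input_size: int = 256
    levels: int = 5
    base_channels: int = 64
    res_blocks_per_level: int = 2
    dilation_rates: tuple = (3, 6, 12)
    fusion_mode: str = "concat_project"

    def __post_init__(self):
        self.dilation_rates = tuple(int(r) for r in self.dilation_rates)
        if self.input_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.levels}"
            )
        if self.bottleneck_size < 4:
            raise ValueError(
                f"bottleneck {self.bottleneck_size} < 4; reduce levels"
            )
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if list(self.dilation_rates) != sorted(set(self.dilation_rates)):
            raise ValueError("dilation rates must be strictly increasing")
        if self.fusion_mode not in ("concat_project", "sum"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // (2 ** self.levels)

    def channels_at(self, level: int) -> int:
        return min(self.base_channels * (2 ** level), MAX_CHANNELS)


@dataclass
class EdgeNetConfig:
    depth: int = 4
    base_channels: int = 32

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("edge net needs depth >= 2")


@dataclass
class DiscriminatorConfig:
    n_layers: int = 3
    base_channels: int = 64

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("discriminator needs n_layers >= 1")


@dataclass
class FeatureMap:
    """A C x H x W activation grid tagged with its encoder level of origin."""

    values: np.ndarray
    level_tag: int = 0


# -- functional primitives -------------------------------------------------

def _as_nchw(p) -> tuple[Tensor, int]:
    """Lift 2-D (H,W) or 3-D (C,H,W) inputs to N,C,H,W; report original ndim."""
    t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    ndim = t.ndim
    for _ in range(4 - ndim):
        inner = t

        def bw(g, inner=inner):
            if inner.requires_grad:
                inner._accum(g[0])

        t = Tensor._result(t.data[None], (inner,), bw)
    return t, ndim


def _squeeze_back(out: Tensor, ndim: int) -> Tensor:
    for _ in range(4 - ndim):
        parent = out

        def bw(g, parent=parent):
            parent._accum(g[None])

        out = Tensor._result(out.data[0], (parent,), bw)
    return out


def dilated_conv(p, kernel, rate: int):
    """Dilated 2-D convolution with taps spaced ``rate`` pixels apart.

    output(s) = sum_{a + rate*b = s} P(a) k(b), zero-padded so the spatial
    size is preserved (pad = kernel_radius * rate per side for odd kernels).
    Accepts 2-D, C,H,W or N,C,H,W inputs; ``kernel`` is either (kh, kw) for
    a single channel or (out_ch, in_ch, kh, kw).
    """
    if rate < 1:
        raise ValueError(f"dilation rate must be positive, got {rate}")
    t, ndim = _as_nchw(p)
    k, _ = _as_nchw(kernel)
    kh, kw = k.data.shape[-2:]
    out = ad.conv2d(t, k, padding=same_padding(kh, kw, rate), dilation=rate)
    return _squeeze_back(out, ndim)


def g2l_fuse(p, kernels, rates, fusion_mode: str = "sum", proj_kernels=None):
    """Global-to-local fusion of multi-rate dilated-convolution branches.

    Each branch convolves ``p`` with its own kernel at its rate; aggregation
    starts from the largest rate (the most global context) and folds in
    progressively more local branches:
    ``fused = branch(t_max); fused = op(branch(t), fused)`` for each smaller
    rate. ``op`` is addition for ``fusion_mode='sum'`` or channel
    concatenation followed by a 1x1 projection (``proj_kernels``, one per
    fold, each (C, 2C, 1, 1)) for ``'concat_project'``.
    """
    rates = list(rates)
    if len(kernels) != len(rates):
        raise ValueError("one kernel per rate required")
    if not rates:
        raise ValueError("at least one dilation rate required")
    t, ndim = _as_nchw(p)
    branches = {}
    shape = None
    for k, r in zip(kernels, rates):
        b = dilated_conv(t, k, r)
        if shape is None:
            shape = b.data.shape
        elif b.data.shape != shape:
            raise ValueError("fusion branches disagree in shape")
        branches[r] = b
    order = sorted(rates, reverse=True)
    fused = branches[order[0]]
    for i, r in enumerate(order[1:]):
        if fusion_mode == "sum":
            fused = branches[r] + fused
        elif fusion_mode == "concat_project":
            if proj_kernels is None:
                raise ValueError("concat_project needs proj_kernels")
            pk, _ = _as_nchw(proj_kernels[i])
            fused = ad.conv2d(ad.concat_channels([branches[r], fused]), pk)
        else:
            raise ValueError(f"unknown fusion_mode {fusion_mode!r}")
    return _squeeze_back(fused, ndim)


# -- fusion / upsampling modules ------------------------------------------

class GlobalLocalFusion(Module):
    """Learned multi-rate dilated fusion applied on a skip pathway."""

    def __init__(self, channels: int, rates, mode: str, rng: np.random.Generator):
        self.rates = sorted(rates, reverse=True)
        self.mode = mode
        self.branches = [
            Conv2d(channels, channels, 3, rng, dilation=r) for r in self.rates
        ]
        if mode == "concat_project":
            self.projections = [
                Conv2d(2 * channels, channels, 1, rng) for _ in self.rates[1:]
            ]
        else:
            self.projections = []

    def forward(self, x: Tensor) -> Tensor:
        fused = self.branches[0](x)
        for i, conv in enumerate(self.branches[1:]):
            local = conv(x)
            if self.mode == "sum":
                fused = local + fused
            else:
                fused = self.projections[i](ad.concat_channels([local, fused]))
        return fused


class UpsampleBlock(Module):
    """Dual-branch interleaved upsampler doubling H and W.

    Branch 1 applies four convolutions with 2x2, 3x2, 2x3 and 3x3 kernels
    (asymmetric trailing-edge padding keeps each output H x W) and places
    them at sub-pixel phases (even,even), (odd,even), (even,odd), (odd,odd).
    Branch 2 does the same with four 5x5 convolutions. The branches are
    summed elementwise.
    """

    BRANCH1_KERNELS = ((2, 2), (3, 2), (2, 3), (3, 3))

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.branch1 = [Conv2d(in_ch, out_ch, k, rng) for k in self.BRANCH1_KERNELS]
        self.branch2 = [Conv2d(in_ch, out_ch, 5, rng) for _ in range(4)]

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] < 2 or x.shape[-2] < 2:
            raise ValueError("upsample block needs at least 2x2 input")
        b1 = ad.interleave2x(*(conv(x) for conv in self.branch1))
        b2 = ad.interleave2x(*(conv(x) for conv in self.branch2))
        return b1 + b2


# -- generator -------------------------------------------------------------

class Generator(Module):
    """Encoder-decoder translator with dilated skip fusion.

    Input and output are single-channel N,1,H,W tensors on the network scale
    [-1, 1]; the output activation is tanh. The forward pass asserts the
    contracted bottleneck size internally.
    """

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = [cfg.channels_at(i) for i in range(cfg.levels + 1)]
        self.stem = ConvNormRelu(1, ch[0], 3, rng)
        self.down = []
        self.res = []
        for i in range(1, cfg.levels + 1):
            self.down.append(
                ConvNormRelu(ch[i - 1], ch[i], 3, rng, stride=2, padding=(0, 1, 0, 1))
            )
            self.res.append(
                [ResidualBlock(ch[i], rng) for _ in range(cfg.res_blocks_per_level)]
            )
        self.fusion = [
            GlobalLocalFusion(ch[i], cfg.dilation_rates, cfg.fusion_mode, rng)
            for i in range(cfg.levels + 1)
        ]
        self.up = [
            UpsampleBlock(ch[i + 1], ch[i], rng) for i in range(cfg.levels)
        ]
        self.merge = [Conv2d(2 * ch[i], ch[i], 1, rng) for i in range(cfg.levels)]
        self.head = Conv2d(ch[0], 1, 3, rng, gain=1.0)

    def forward(self, x: Tensor) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected N,1,H,W input, got shape {x.shape}")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"input is {x.shape[2]}x{x.shape[3]}, "
                f"config expects {self.cfg.input_size}"
            )
        skips = []
        h = self.stem(x)
        skips.append(h)
        for down, blocks in zip(self.down, self.res):
            h = down(h)
            for block in blocks:
                h = block(h)
            skips.append(h)
        assert h.shape[-1] == self.cfg.bottleneck_size, (
            f"bottleneck is {h.shape[-1]}, expected {self.cfg.bottleneck_size}"
        )
        d = self.fusion[self.cfg.levels](skips[-1])
        for i in range(self.cfg.levels - 1, -1, -1):
            d = self.up[i](d)
            skip = self.fusion[i](skips[i])
            d = self.merge[i](ad.concat_channels([skip, d]))
        return ad.tanh(self.head(d))

    def translate(self, images: np.ndarray) -> np.ndarray:
        """Inference on a batch of H x W (or N,H,W) network-scale arrays."""
        arr = np.asarray(images, dtype=np.float64)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        with ad.no_grad():
            out = self.forward(Tensor(arr[:, None])).data[:, 0]
        return out[0] if single else out


# -- discriminator ---------------------------------------------------------

class PatchDiscriminator(Module):
    """PatchGAN: strided conv stack emitting a grid of raw patch scores."""

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.convs = []
        self.norms = []
        in_ch = 1
        ch = cfg.base_channels
        for i in range(cfg.n_layers):
            self.convs.append(
                Conv2d(in_ch, ch, 4, rng, stride=2, padding=(1, 1, 1, 1))
            )
            self.norms.append(InstanceNorm2d(ch) if i > 0 else None)
            in_ch, ch = ch, min(ch * 2, MAX_CHANNELS)
        self.penult = Conv2d(in_ch, ch, 4, rng, stride=1, padding=(1, 1, 1, 1))
        self.penult_norm = InstanceNorm2d(ch)
        self.final = Conv2d(ch, 1, 4, rng, stride=1, padding=(1, 1, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        h = ad.as_tensor(x)
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = ad.leaky_relu(h, 0.2)
        h = ad.leaky_relu(self.penult_norm(self.penult(h)), 0.2)
        return self.final(h)


# -- edge detector ---------------------------------------------------------

class EdgeUNet(Module):
    """U-Net edge detector; ``forward`` returns logits, ``edge_map`` in [0,1]."""

    def __init__(self, cfg: EdgeNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        ch = [min(cfg.base_channels * 2 ** i, MAX_CHANNELS) for i in range(cfg.depth)]
        self.enc = [ConvNormRelu(1, ch[0], 3, rng)]
        self.downs = []
        for i in range(1, cfg.depth):
            self.downs.append(
                ConvNormRelu(ch[i - 1], ch[i], 3, rng, stride=2, padding=(0, 1, 0, 1))
            )
            self.enc.append(ConvNormRelu(ch[i], ch[i], 3, rng))
        self.ups = []
        self.dec = []
        for i in range(cfg.depth - 2, -1, -1):
            self.ups.append(Conv2d(ch[i + 1], ch[i], 3, rng))
            self.dec.append(ConvNormRelu(2 * ch[i], ch[i], 3, rng))
        self.head = Conv2d(ch[0], 1, 1, rng, gain=1.0)

    def forward(self, x: Tensor) -> Tensor:
        x = ad.as_tensor(x)
        if x.shape[-1] % 2 ** (self.cfg.depth - 1) or x.shape[-2] % 2 ** (self.cfg.depth - 1):
            raise ValueError(
                f"input size must be divisible by {2 ** (self.cfg.depth - 1)}"
            )
        skips = []
        h = self.enc[0](x)
        skips.append(h)
        for down, enc in zip(self.downs, self.enc[1:]):
            h = enc(down(h))
            skips.append(h)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips[:-1])):
            h = up(ad.upsample_nearest2x(h))
            h = dec(ad.concat_channels([skip, h]))
        return self.head(h)

    def edge_map(self, x) -> Tensor:
        return ad.sigmoid(self.forward(x))

    def edge_map_array(self, images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        with ad.no_grad():
            out = self.edge_map(Tensor(arr[:, None])).data[:, 0]
        return out[0] if single else out


# -- checkpoints -----------------------------------------------------------

_KIND_BUILDERS = {
    "generator": (GeneratorConfig, Generator),
    "discriminator": (DiscriminatorConfig, PatchDiscriminator),
    "edge_net": (EdgeNetConfig, EdgeUNet),
}


def save_checkpoint(path, kind: str, cfg, model: Module, rng_state=None):
    """Persist config + weights (+ optional RNG state) to an .npz file.

    The architecture is rebuilt from the config alone on load, so the file
    is forward-compatible with weight-layout-preserving code changes.
    """
    if kind not in _KIND_BUILDERS:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    header = {"kind": kind, "config": asdict(cfg), "format_version": 1}
    if rng_state is not None:
        header["rng_state"] = rng_state
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez(fh, header=json.dumps(header), **arrays)


def load_checkpoint(path, frozen: bool = False):
    """Rebuild (kind, config, model) from a checkpoint file."""
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        arrays = [npz[f"param_{i}"] for i in range(len(npz.files) - 1)]
    kind = header["kind"]
    cfg_cls, model_cls = _KIND_BUILDERS[kind]
    cfg_dict = dict(header["config"])
    if "dilation_rates" in cfg_dict:
        cfg_dict["dilation_rates"] = tuple(cfg_dict["dilation_rates"])
    cfg = cfg_cls(**cfg_dict)
    model = model_cls(cfg, np.random.default_rng(0))
    model.load_state_arrays(arrays)
    if frozen:
        model.freeze()
    return kind, cfg, model
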