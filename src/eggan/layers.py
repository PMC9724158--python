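"""Parameterised network building blocks (conv layers, norms, residual blocks).

Weight initialisation is He-normal drawn from an explicit ``numpy.random
.Generator`` so every network build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def same_padding(kh: int, kw: int, dilation: int = 1) -> tuple[int, int, int, int]:
    """Zero padding keeping spatial size at stride 1.

    Total pad per axis is (k-1)*dilation; for even kernels the extra pixel
    goes on the trailing edge (bottom/right), so e.g. a 2x2 kernel pads
    (0, 1, 0, 1) and rectangular 3x2 / 2x3 kernels stay exactly H x W.
    """
    th = (kh - 1) * dilation
    tw = (kw - 1) * dilation
    return th // 2, th - th // 2, tw // 2, tw - tw // 2


class Module:
    """Minimal container: registers child modules and Tensor parameters.

    Attributes that are Tensors, Modules, or (nested) lists/tuples of either
    are discovered in deterministic attribute-insertion order.
    """

    def _walk(self):
        def visit(value):
            if isinstance(value, Tensor):
                yield value
            elif isinstance(value, Module):
                for v in vars(value).values():
                    yield from visit(v)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    yield from visit(v)

        yield from visit(self)

    def parameters(self) -> list[Tensor]:
        seen: set[int] = set()
        params: list[Tensor] = []
        for t in self._walk():
            if t.requires_grad and id(t) not in seen:
                seen.add(id(t))
                params.append(t)
        return params

    def all_tensors(self) -> list[Tensor]:
        """All parameter tensors regardless of requires_grad (for freezing/IO)."""
        return list(self._walk())

    def freeze(self):
        for t in self.all_tensors():
            t.requires_grad = False
        return self

    def state_arrays(self) -> list[np.ndarray]:
        return [t.data for t in self.all_tensors()]

    def load_state_arrays(self, arrays):
        tensors = self.all_tensors()
        if len(arrays) != len(tensors):
            raise ValueError(
                f"state has {len(arrays)} arrays, model expects {len(tensors)}"
            )
        for t, a in zip(tensors, arrays):
            if t.data.shape != a.shape:
                raise ValueError(f"shape mismatch {t.data.shape} vs {a.shape}")
            t.data = np.asarray(a, dtype=np.float64).copy()

    def checksum(self) -> float:
        return float(sum(np.abs(t.data).sum() for t in self.all_tensors()))

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, rng: np.random.Generator,
                 stride: int = 1, dilation: int = 1, padding="same",
                 bias: bool = True, gain: float = 2.0):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if padding == "same":
            padding = same_padding(kh, kw, dilation)
        self.stride, self.dilation, self.padding = stride, dilation, padding
        fan_in = in_ch * kh * kw
        std = np.sqrt(gain / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kh, kw)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride,
                         dilation=self.dilation, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=affine)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=affine)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc / ad.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta


class ConvNormRelu(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, padding="same"):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, stride=stride, padding=padding)
        self.norm = InstanceNorm2d(out_ch)

    def forward(self, x):
        return ad.relu(self.norm(self.conv(x)))


class ResidualBlock(Module):
    """conv-norm-ReLU, conv-norm, additive skip, final ReLU."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return ad.relu(h + x)
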