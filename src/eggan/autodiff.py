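"""Compact reverse-mode automatic differentiation on numpy arrays.

Provides the small set of differentiable operations the translation networks
need: broadcasting arithmetic, pointwise nonlinearities, reductions, 2-D
convolution (strided and dilated, im2col-based), sub-pixel interleaving,
nearest-neighbour upsampling, channel concatenation, forward-difference image
gradients and a numerically stable binary cross-entropy. Everything runs in
float64 so oracle comparisons hold to tight tolerances.

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar. Graph construction is skipped entirely inside ``no_grad()`` or when no
input requires gradients, which keeps inference cheap.
"""

from __future__ import annotations

import numpy as np

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._result(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._result(data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise functions ---------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._result(x.data * mask, (x,), bw)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(x.data > 0, 1.0, slope)

    def bw(g):
        if x.requires_grad:
            x._accum(g * factor)

    return Tensor._result(x.data * factor, (x,), bw)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    return Tensor._result(t, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor._result(s, (x,), bw)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def bw(g):
        if x.requires_grad:
            x._accum(g * 0.5 / np.maximum(r, 1e-300))

    return Tensor._result(r, (x,), bw)


def absolute(x: Tensor) -> Tensor:
    s = np.sign(x.data)  # subgradient 0 at 0

    def bw(g):
        if x.requires_grad:
            x._accum(g * s)

    return Tensor._result(np.abs(x.data), (x,), bw)


def square(x: Tensor) -> Tensor:
    return x * x


# -- structural ops --------------------------------------------------------

def concat_channels(tensors) -> Tensor:
    """Concatenate N,C,H,W tensors along the channel axis."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(g[:, lo:hi])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=1), tensors, bw)


def pad2d(x: Tensor, pads) -> Tensor:
    """Zero-pad the last two axes; pads = (top, bottom, left, right)."""
    pt, pb, pl, pr = pads
    widths = [(0, 0)] * (x.data.ndim - 2) + [(pt, pb), (pl, pr)]
    h, w = x.data.shape[-2:]

    def bw(g):
        if x.requires_grad:
            x._accum(g[..., pt:pt + h, pl:pl + w])

    return Tensor._result(np.pad(x.data, widths), (x,), bw)


def interleave2x(ee: Tensor, oe: Tensor, eo: Tensor, oo: Tensor) -> Tensor:
    """Assemble a 2H x 2W map from four H x W phase maps.

    Phases are (row parity, column parity): ``ee`` fills (even, even),
    ``oe`` (odd, even), ``eo`` (even, odd), ``oo`` (odd, odd).
    """
    parts = (ee, oe, eo, oo)
    n, c, h, w = ee.data.shape
    out = np.empty((n, c, 2 * h, 2 * w), dtype=np.float64)
    out[..., 0::2, 0::2] = ee.data
    out[..., 1::2, 0::2] = oe.data
    out[..., 0::2, 1::2] = eo.data
    out[..., 1::2, 1::2] = oo.data

    def bw(g):
        if ee.requires_grad:
            ee._accum(g[..., 0::2, 0::2])
        if oe.requires_grad:
            oe._accum(g[..., 1::2, 0::2])
        if eo.requires_grad:
            eo._accum(g[..., 0::2, 1::2])
        if oo.requires_grad:
            oo._accum(g[..., 1::2, 1::2])

    return Tensor._result(out, parts, bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    data = x.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def bw(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._result(data, (x,), bw)


def grad_x(x: Tensor) -> Tensor:
    """Forward difference along the last (column) axis; last column is 0."""
    d = np.zeros_like(x.data)
    d[..., :, :-1] = x.data[..., :, 1:] - x.data[..., :, :-1]

    def bw(g):
        if x.requires_grad:
            gg = np.zeros_like(x.data)
            gg[..., :, 1:] += g[..., :, :-1]
            gg[..., :, :-1] -= g[..., :, :-1]
            x._accum(gg)

    return Tensor._result(d, (x,), bw)


def grad_y(x: Tensor) -> Tensor:
    """Forward difference along the row axis; last row is 0."""
    d = np.zeros_like(x.data)
    d[..., :-1, :] = x.data[..., 1:, :] - x.data[..., :-1, :]

    def bw(g):
        if x.requires_grad:
            gg = np.zeros_like(x.data)
            gg[..., 1:, :] += g[..., :-1, :]
            gg[..., :-1, :] -= g[..., :-1, :]
            x._accum(gg)

    return Tensor._result(d, (x,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores, numerically stable."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float64)
    # log(1 + e^-|z|) + max(z, 0) - z*t
    loss = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * t
    n = z.size

    def bw(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accum(g * (s - t) / n)

    return Tensor._result(loss.mean(), (logits,), bw)


# -- convolution -----------------------------------------------------------

def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
    padding=(0, 0, 0, 0),
) -> Tensor:
    """2-D convolution (cross-correlation) over N,C,H,W input.

    ``padding`` is (top, bottom, left, right) zero padding; ``dilation``
    spaces kernel taps ``dilation`` pixels apart.
    """
    if dilation < 1:
        raise ValueError(f"dilation must be >= 1, got {dilation}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    pt, pb, pl, pr = padding
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, kernel expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    ekh = (kh - 1) * dilation + 1
    ekw = (kw - 1) * dilation + 1
    hp, wp = xp.shape[-2:]
    if hp < ekh or wp < ekw:
        raise ValueError("input smaller than effective kernel size")
    oh = (hp - ekh) // stride + 1
    ow = (wp - ekw) // stride + 1

    win = np.lib.stride_tricks.sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # N,C,oh,ow,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, cin * kh * kw
    )
    wmat = weight.data.reshape(cout, -1)
    out = (cols @ wmat.T).reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, cout)
        if weight.requires_grad:
            weight._accum((gmat.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(n, oh, ow, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :,
                        :,
                        i * dilation:i * dilation + oh * stride:stride,
                        j * dilation:j * dilation + ow * stride:stride,
                    ] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accum(gxp[:, :, pt:pt + h, pl:pl + w])

    return Tensor._result(out, parents, bw)


# -- optimizers ------------------------------------------------------------

class Adam:
    """Adam with configurable first-moment decay (the training "momentum")."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGDMomentum:
    def __init__(self, params, lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= self.lr * b

    def zero_grad(self):
        for p in self.params:
            p.grad = None
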