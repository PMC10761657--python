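"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical engine behind the restoration networks: a
:class:`Tensor` wrapping an ``ndarray`` with a gradient slot, a handful of
differentiable operations (3D convolution, leaky ReLU, channel concatenation,
zero-stuffing upsampling, elementwise arithmetic, mean-squared error) and an
Adam optimizer.  Volumes flow through the graph in channels-last layout
``(N, H, W, D, C)``; convolutions are evaluated as an im2col matrix product so
the heavy lifting is a single BLAS GEMM per layer.

Only what the networks need is implemented; this is not a general framework.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "leaky_relu",
    "concat",
    "upsample2x",
    "mse",
    "Conv3d",
    "Adam",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # free the closure so cached im2col buffers are reclaimed
            node._backward = None

    # -- elementwise arithmetic --------------------------------------------
    def __add__(self, other):
        if not isinstance(other, Tensor):
            out = Tensor(self.data + other)
            out._parents = (self,)

            def _bw(s=self, o=out):
                s._accumulate(o.grad)

            out._backward = _bw
            return out
        out = Tensor(self.data + other.data)
        out._parents = (self, other)

        def _bw(a=self, b=other, o=out):
            a._accumulate(o.grad)
            b._accumulate(o.grad)

        out._backward = _bw
        return out

    def __sub__(self, other):
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data - other_t.data)
        out._parents = (self, other_t)

        def _bw(a=self, b=other_t, o=out):
            a._accumulate(o.grad)
            b._accumulate(-o.grad)

        out._backward = _bw
        return out

    def __mul__(self, scalar: float):
        out = Tensor(self.data * scalar)
        out._parents = (self,)

        def _bw(s=self, o=out, k=scalar):
            s._accumulate(o.grad * k)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _im2col(xd: np.ndarray, kshape: tuple[int, int, int],
            sh: int, sw: int) -> np.ndarray:
    """'Same'-padded im2col of a ``(N,H,W,D,C)`` array.

    Returns a ``(N*Ho*Wo*D, KH*KW*KD*C)`` matrix whose columns are ordered
    offset-major then channel, matching ``w.reshape(-1, O)``.
    """
    N, H, W, D, C = xd.shape
    KH, KW, KD = kshape
    ph, pw, pd = KH // 2, KW // 2, KD // 2
    xp = np.pad(xd, ((0, 0), (ph, ph), (pw, pw), (pd, pd), (0, 0)))
    swv = np.lib.stride_tricks.sliding_window_view(
        xp, (KH, KW, KD), axis=(1, 2, 3))        # (N,H,W,D,C,KH,KW,KD)
    swv = swv[:, ::sh, ::sw]
    Ho, Wo = swv.shape[1], swv.shape[2]
    return (swv.transpose(0, 1, 2, 3, 5, 6, 7, 4)
               .reshape(N * Ho * Wo * D, KH * KW * KD * C))


def _conv3d_raw(xd: np.ndarray, wd: np.ndarray, bd: np.ndarray | None,
                sh: int, sw: int):
    """Forward convolution; returns the output and the im2col matrix."""
    N, H, W, D, C = xd.shape
    KH, KW, KD, Ci, O = wd.shape
    col = _im2col(xd, (KH, KW, KD), sh, sw)
    y = col @ wd.reshape(-1, O)
    if bd is not None:
        y += bd
    return y.reshape(N, H // sh, W // sw, D, O), col


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: tuple[int, int] = (1, 1)) -> Tensor:
    """'Same'-padded 3D convolution of ``(N,H,W,D,C)`` by ``(kh,kw,kd,C,O)``.

    Striding applies in-plane only (H, W); the depth axis always keeps its
    length, matching networks that never collapse the slab depth.
    """
    xd, wd = x.data, w.data
    N, H, W, D, C = xd.shape
    KH, KW, KD, Ci, O = wd.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    sh, sw = stride
    if H % sh or W % sw:
        raise ValueError("in-plane dims must be divisible by the stride")
    yd, col = _conv3d_raw(xd, wd, b.data if b is not None else None, sh, sw)
    out = Tensor(yd)
    parents = [x, w] + ([b] if b is not None else [])
    out._parents = tuple(parents)

    def _bw(x=x, w=w, b=b, o=out, col=col, dims=(sh, sw, O)):
        sh, sw, O = dims
        dy = o.grad
        dyf = dy.reshape(-1, O)
        if w.requires_grad:
            w._accumulate((col.T @ dyf).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(dyf.sum(axis=0))
        if not (x.requires_grad or x._parents):
            return
        # grad wrt input = convolution of (zero-stuffed) dy with the
        # spatially flipped kernel, channel axes transposed
        if sh != 1 or sw != 1:
            Nn, Ho, Wo, D, _ = dy.shape
            u = np.zeros((Nn, Ho * sh, Wo * sw, D, O), dtype=dy.dtype)
            u[:, ::sh, ::sw] = dy
        else:
            u = dy
        w_flip = w.data[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
        dx, _ = _conv3d_raw(u, np.ascontiguousarray(w_flip), None, 1, 1)
        x._accumulate(dx)

    out._backward = _bw
    return out


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    xd = x.data
    out = Tensor(np.where(xd >= 0, xd, negative_slope * xd))
    out._parents = (x,)

    def _bw(x=x, o=out, a=negative_slope):
        x._accumulate(np.where(x.data >= 0, o.grad, a * o.grad))

    out._backward = _bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two tensors along the channel (last) axis."""
    ca = a.data.shape[-1]
    out = Tensor(np.concatenate([a.data, b.data], axis=-1))
    out._parents = (a, b)

    def _bw(a=a, b=b, o=out, ca=ca):
        a._accumulate(o.grad[..., :ca])
        b._accumulate(o.grad[..., ca:])

    out._backward = _bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Zero-stuffing ×2 in-plane upsampling (transposed-conv front half)."""
    N, H, W, D, C = x.data.shape
    y = np.zeros((N, 2 * H, 2 * W, D, C), dtype=x.data.dtype)
    y[:, ::2, ::2] = x.data
    out = Tensor(y)
    out._parents = (x,)

    def _bw(x=x, o=out):
        x._accumulate(o.grad[:, ::2, ::2])

    out._backward = _bw
    return out


def mse(pred: Tensor, target) -> Tensor:
    """Mean squared error over every element; target carries no gradient."""
    td = target.data if isinstance(target, Tensor) else np.asarray(target)
    diff = pred.data - td
    out = Tensor(np.asarray(diff.dtype.type(np.mean(diff * diff))))
    out._parents = (pred,)

    def _bw(p=pred, o=out, diff=diff):
        p._accumulate((2.0 / diff.size) * diff * o.grad)

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# layers and optimizer
# ---------------------------------------------------------------------------

class Conv3d:
    """A 3D convolution layer with He-initialised weights and a bias."""

    def __init__(self, c_in: int, c_out: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 stride: tuple[int, int] = (1, 1),
                 rng: np.random.Generator | None = None,
                 trainable: bool = True,
                 dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        kh, kw, kd = kernel
        fan_in = kh * kw * kd * c_in
        scale = math.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, scale,
                                   size=(kh, kw, kd, c_in, c_out)).astype(dtype),
                        requires_grad=trainable)
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=trainable)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b] if self.w.requires_grad else []

    def n_parameters(self) -> int:
        return self.w.data.size + self.b.data.size


class Adam:
    """Adam optimizer over a fixed list of :class:`Tensor` parameters."""

    def __init__(self, params: Sequence[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
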