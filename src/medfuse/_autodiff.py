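"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the fusion network needs — same-padded 2-D
convolution, ReLU/sigmoid, channel concatenation, global spatial pooling,
per-pixel channel pooling, broadcasting arithmetic and reductions — on a
micrograd-style tape.  Array layout is channels-last: (N, H, W, C).

Gradients are plain numpy arrays accumulated on ``Tensor.grad``; nodes whose
inputs do not require gradients record nothing, so inference pays no tape
overhead.  Convolution is evaluated as one GEMM per kernel offset, which for
the 1x1/3x3/7x7 kernels used here is both fast and exactly reproducible
run-to-run on CPU.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "sigmoid",
    "concat",
    "spatial_max_pool",
    "spatial_avg_pool",
    "channel_max_pool",
    "channel_avg_pool",
]


class Tensor:
    """A numpy array plus the closure that propagates gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Reverse sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda a, b, g: (g * b, g * a))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def sum(self) -> "Tensor":
        out_data = self.data.sum(keepdims=False)
        if not self.requires_grad:
            return Tensor(out_data)

        def bwd(g):
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, True, (self,), bwd)

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a, b, fwd, grads) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = fwd(a.data, b.data)
    if not (a.requires_grad or b.requires_grad):
        return Tensor(out_data)

    def bwd(g):
        ga, gb = grads(a.data, b.data, g)
        if a.requires_grad:
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, True, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    x = _wrap(x)
    out_data = np.maximum(x.data, 0)
    if not x.requires_grad:
        return Tensor(out_data)
    mask = x.data > 0

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(out_data, True, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = _wrap(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    if not x.requires_grad:
        return Tensor(s)

    def bwd(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor(s, True, (x,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(out_data, True, tuple(tensors), bwd)


def _pad_spatial(data: np.ndarray, ph: int, pw: int, mode: str) -> np.ndarray:
    if ph == 0 and pw == 0:
        return data
    pad_mode = "constant" if mode == "zero" else "reflect"
    return np.pad(data, ((0, 0), (ph, ph), (pw, pw), (0, 0)), mode=pad_mode)


def _unpad_grad(gpad: np.ndarray, H: int, W: int, ph: int, pw: int, mode: str) -> np.ndarray:
    if ph == 0 and pw == 0:
        return gpad
    if mode == "zero":
        return gpad[:, ph : ph + H, pw : pw + W, :]
    # reflect: fold every padded position's gradient back onto its source pixel
    idx = np.pad(
        np.arange(H * W).reshape(H, W), ((ph, ph), (pw, pw)), mode="reflect"
    ).ravel()
    N, C = gpad.shape[0], gpad.shape[3]
    out = np.zeros((N, H * W, C), dtype=gpad.dtype)
    for n in range(N):
        np.add.at(out[n], idx, gpad[n].reshape(-1, C))
    return out.reshape(N, H, W, C)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: str = "zero") -> Tensor:
    """Stride-1, same-padded 2-D convolution (cross-correlation).

    ``x`` is (N, H, W, Cin), ``w`` is (kh, kw, Cin, Cout) with odd kernel
    sides, ``b`` is (Cout,).  ``padding`` is "zero" or "reflect".
    """
    x, w = _wrap(x), _wrap(w)
    kh, kw, cin, cout = w.data.shape
    if x.data.ndim != 4 or x.data.shape[3] != cin:
        raise ValueError(
            f"input shape {x.data.shape} incompatible with kernel {w.data.shape}"
        )
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("only odd kernel sides are supported")
    N, H, W, _ = x.data.shape
    ph, pw = kh // 2, kw // 2
    w_mat = w.data.reshape(kh * kw * cin, cout)
    if kh == 1 and kw == 1:
        col = x.data.reshape(-1, cin)
    else:
        xp = _pad_spatial(x.data, ph, pw, padding)
        col = np.empty((N * H * W, kh * kw * cin), dtype=x.data.dtype)
        for di in range(kh):
            for dj in range(kw):
                k = (di * kw + dj) * cin
                col[:, k : k + cin] = xp[:, di : di + H, dj : dj + W, :].reshape(
                    -1, cin
                )
    out_data = (col @ w_mat).reshape(N, H, W, cout)
    if b is not None:
        b = _wrap(b)
        out_data += b.data
    parents = (x, w) if b is None else (x, w, b)
    if not any(p.requires_grad for p in parents):
        return Tensor(out_data)

    def bwd(g):
        gflat = g.reshape(-1, cout)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            w._accumulate((col.T @ gflat).reshape(kh, kw, cin, cout))
        if x.requires_grad:
            gcol = gflat @ w_mat.T
            if kh == 1 and kw == 1:
                x._accumulate(gcol.reshape(N, H, W, cin))
                return
            gxp = np.zeros((N, H + 2 * ph, W + 2 * pw, cin), dtype=g.dtype)
            for di in range(kh):
                for dj in range(kw):
                    k = (di * kw + dj) * cin
                    gxp[:, di : di + H, dj : dj + W, :] += gcol[
                        :, k : k + cin
                    ].reshape(N, H, W, cin)
            x._accumulate(_unpad_grad(gxp, H, W, ph, pw, padding))

    return Tensor(out_data, True, parents, bwd)


def spatial_max_pool(x: Tensor) -> Tensor:
    """Global max over H and W -> (N, 1, 1, C)."""
    x = _wrap(x)
    N, H, W, C = x.data.shape
    flat = x.data.reshape(N, H * W, C)
    idx = flat.argmax(axis=1)
    out_data = np.take_along_axis(flat, idx[:, None, :], axis=1).reshape(N, 1, 1, C)
    if not x.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[:, None, :], g.reshape(N, 1, C), axis=1)
        x._accumulate(gx.reshape(N, H, W, C))

    return Tensor(out_data, True, (x,), bwd)


def spatial_avg_pool(x: Tensor) -> Tensor:
    """Global mean over H and W -> (N, 1, 1, C)."""
    x = _wrap(x)
    N, H, W, C = x.data.shape
    out_data = x.data.mean(axis=(1, 2), keepdims=True)
    if not x.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        x._accumulate(np.broadcast_to(g / (H * W), x.data.shape))

    return Tensor(out_data, True, (x,), bwd)


def channel_max_pool(x: Tensor) -> Tensor:
    """Per-pixel max over channels -> (N, H, W, 1)."""
    x = _wrap(x)
    idx = x.data.argmax(axis=3)
    out_data = np.take_along_axis(x.data, idx[..., None], axis=3)
    if not x.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx[..., None], g, axis=3)
        x._accumulate(gx)

    return Tensor(out_data, True, (x,), bwd)


def channel_avg_pool(x: Tensor) -> Tensor:
    """Per-pixel mean over channels -> (N, H, W, 1)."""
    x = _wrap(x)
    C = x.data.shape[3]
    out_data = x.data.mean(axis=3, keepdims=True)
    if not x.requires_grad:
        return Tensor(out_data)

    def bwd(g):
        x._accumulate(np.broadcast_to(g / C, x.data.shape))

    return Tensor(out_data, True, (x,), bwd)
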